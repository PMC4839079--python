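"""Small-RNA analysis: read collapsing, length profiling, count matrices,
exact mature-miRNA matching and the target anticorrelation filter."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stagewise.config import PipelineConfig
from stagewise.design import ExperimentDesign
from stagewise.matrix import CountMatrix, ExpressionMatrix

_VALID = set("ACGTN")


@dataclass
class SRNALibrary:
    """Distinct sRNA sequences with read counts for one library."""

    library_id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def collapse(
    reads, library_id: str = "lib", retain_gt_len: int = 15
) -> SRNALibrary:
    """Collapse reads to distinct sequences with multiplicities.

    Reads of length <= *retain_gt_len* are dropped (only reads strictly
    longer are retained). Invalid characters are an error.
    """
    counter: Counter[str] = Counter()
    for seq in reads:
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"invalid characters {bad} in read {seq!r}")
        if len(seq) > retain_gt_len:
            counter[seq] += 1
    return SRNALibrary(library_id=library_id, counts=dict(counter))


def length_profile(
    lib: SRNALibrary, min_len: int = 18, max_len: int = 28, distinct: bool = False
) -> dict[int, int]:
    """Read (or distinct-sequence) counts per length inside the window."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    profile: dict[int, int] = {}
    for seq, count in lib.counts.items():
        n = len(seq)
        if min_len <= n <= max_len:
            profile[n] = profile.get(n, 0) + (1 if distinct else count)
    return dict(sorted(profile.items()))


def build_count_matrix(
    libs: list[SRNALibrary],
    design: ExperimentDesign,
    min_len: int = 18,
    max_len: int = 28,
) -> CountMatrix:
    """Union of in-window distinct sequences x libraries; absent -> 0.

    One library per design sample is required (matched by library_id).
    """
    by_id = {lib.library_id: lib for lib in libs}
    missing = [s for s in design.samples if s not in by_id]
    if missing:
        raise ValueError(f"no sRNA library for samples: {missing}")
    universe: set[str] = set()
    for sample in design.samples:
        universe |= {
            s for s in by_id[sample].counts if min_len <= len(s) <= max_len
        }
    if not universe:
        import warnings

        warnings.warn("length window excludes every sequence; empty matrix")
    index = sorted(universe)
    data = {
        sample: [by_id[sample].counts.get(seq, 0) for seq in index]
        for sample in design.samples
    }
    frame = pd.DataFrame(data, index=index, dtype="int64")
    return CountMatrix(frame, design)


def match_mature_mirna(
    lib: SRNALibrary, mature: list[tuple[str, str]]
) -> dict[str, list[str]]:
    """Exact, gap-free, forward-orientation substring matches.

    An sRNA matches a mature miRNA iff the sRNA sequence occurs verbatim
    inside the mature sequence; all matching miRNA IDs are listed.
    """
    matches: dict[str, list[str]] = {}
    for seq in lib.counts:
        ids = [mid for mid, mseq in mature if seq in mseq]
        if ids:
            matches[seq] = ids
    return matches


@dataclass
class TargetPair:
    """Candidate sRNA -> transcript pairing with its stage-mean correlation."""

    srna_seq: str
    transcript_id: str
    stage_corr: float  # nan when undefined (zero-variance profile)
    srna_de: bool
    target_de: bool
    retained: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc**2).sum()))
    ny = float(np.sqrt((yc**2).sum()))
    if nx == 0 or ny == 0:
        return math.nan
    return float((xc @ yc) / (nx * ny))


def target_anticorrelation_filter(
    pairs: list[tuple[str, str]],
    srna_expr: ExpressionMatrix,
    tx_expr: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    srna_de: set[str] | None = None,
    tx_de: set[str] | None = None,
) -> list[TargetPair]:
    """Retain pairs whose stage-mean profiles are strongly anticorrelated.

    The correlation is Pearson over the per-stage means (one point per
    stage); a zero-variance profile on either side leaves the correlation
    undefined and the pair not retained.
    """
    cfg = cfg or PipelineConfig()
    srna_de = srna_de or set()
    tx_de = tx_de or set()
    if list(srna_expr.design.stage_order) != list(tx_expr.design.stage_order):
        raise ValueError("sRNA and transcript designs disagree on stages")
    srna_means = srna_expr.stage_means()
    tx_means = tx_expr.stage_means()
    out: list[TargetPair] = []
    for seq, tid in pairs:
        if seq not in srna_means.index:
            raise KeyError(f"unknown sRNA {seq!r} in pair table")
        if tid not in tx_means.index:
            raise KeyError(f"unknown transcript {tid!r} in pair table")
        r = _pearson(
            srna_means.loc[seq].to_numpy(), tx_means.loc[tid].to_numpy()
        )
        retained = (not math.isnan(r)) and r <= cfg.target_corr_max
        out.append(
            TargetPair(
                srna_seq=seq,
                transcript_id=tid,
                stage_corr=r,
                srna_de=seq in srna_de,
                target_de=tid in tx_de,
                retained=retained,
            )
        )
    return out
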