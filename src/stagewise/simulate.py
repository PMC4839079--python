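"""Seeded synthetic-data generator with ground-truth labels.

Emulates a 3-stage x 3-replicate staged expression experiment:
overdispersed (negative-binomial) counts with planted fold changes along
twelve up/down/flat profile archetypes, planted GO enrichments per
archetype, sRNA libraries with 21-nt/24-nt abundance peaks and planted
mature-miRNA matches, and sRNA->transcript pair tables with planted
negative stage-mean correlation.

Every generator is deterministic given its seed; sub-streams are derived
from the config seed by fixed offsets so components stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stagewise.design import ExperimentDesign, three_stage_design
from stagewise.matrix import CountMatrix, ExpressionMatrix

# (T1 trend, T2 trend, fold-magnitude scale): the 8 non-flat sign patterns
# over two transitions, with magnitude variants duplicating the four
# dominant patterns to reach 12 archetypes.
ARCHETYPES: tuple[tuple[int, int, float], ...] = (
    (1, 0, 1.0),    # 0: up in T1
    (-1, 0, 1.0),   # 1: down in T1
    (0, 1, 1.0),    # 2: up in T2
    (0, -1, 1.0),   # 3: down in T2
    (1, 1, 1.0),    # 4: steady increase
    (-1, -1, 1.0),  # 5: steady decrease
    (1, -1, 1.0),   # 6: transient up
    (-1, 1, 1.0),   # 7: transient down
    (0, 1, 2.0),    # 8: strong up in T2
    (0, -1, 2.0),   # 9: strong down in T2
    (1, 1, 2.0),    # 10: strong steady increase
    (-1, -1, 2.0),  # 11: strong steady decrease
)

_T1_ONLY = tuple(i for i, a in enumerate(ARCHETYPES) if a[0] != 0 and a[1] == 0)
_T2_ONLY = tuple(i for i, a in enumerate(ARCHETYPES) if a[0] == 0 and a[1] != 0)

# fixed RNG sub-stream offsets, one per generator
_OFF_COUNTS = 11
_OFF_GO = 23
_OFF_SRNA = 37
_OFF_PAIRS = 53


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset."""

    n_features: int = 2000
    replicates: int = 3
    lib_size_mean: float = 200_000.0
    nb_dispersion: float = 0.05
    frac_de_t1: float = 0.05
    frac_de_t2: float = 0.10
    de_fold_range: tuple[float, float] = (2.0, 6.0)
    frac_zero: float = 0.0
    n_go_terms: int = 50
    go_base_rate: float = 0.02
    planted_enriched: list[tuple[int, str, float]] = field(default_factory=list)
    srna_n_distinct: int = 500
    srna_len_weights: dict[int, float] = field(
        default_factory=lambda: {
            16: 1, 17: 1, 18: 2, 19: 2, 20: 3, 21: 8, 22: 3,
            23: 3, 24: 12, 25: 2, 26: 1, 27: 1, 28: 1,
        }
    )
    srna_mean_count: float = 50.0
    srna_frac_trend: float = 0.3  # fraction with up and with down stage trends
    n_planted_mirnas: int = 10
    n_target_pairs: int = 50
    frac_anticorrelated_pairs: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de_t1", "frac_de_t2", "frac_anticorrelated_pairs"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.frac_zero < 1:
            raise ValueError("frac_zero must lie in [0, 1)")
        lo, hi = self.de_fold_range
        if lo < 1 or hi < lo:
            raise ValueError("de_fold_range must satisfy 1 <= low <= high")
        weights = self.srna_len_weights
        if any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise ValueError("length weights must be non-negative, not all zero")

    def design(self) -> ExperimentDesign:
        return three_stage_design(self.replicates)


@dataclass
class SimTruth:
    """Ground-truth labels of a simulated dataset."""

    # transition label -> feature -> (direction, true fold)
    de_features: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)
    archetype_of: dict[str, int] = field(default_factory=dict)
    enriched_pairs: list[tuple[int, str]] = field(default_factory=list)
    mirna_srnas: dict[str, str] = field(default_factory=dict)  # seq -> miRNA id
    anticorrelated_pairs: list[tuple[str, str]] = field(default_factory=list)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with linear overdispersion: var = mu * (1 + dispersion).

    This NB1 parameterization keeps the replicate CV decreasing with the
    mean (CV = sqrt((1 + dispersion) / mu)), matching the filter-cascade
    assumption that well-expressed features have reproducible replicates.
    """
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Generate the transcript-level count matrix and its truth labels."""
    rng = np.random.default_rng(cfg.seed + _OFF_COUNTS)
    design = cfg.design()
    n = cfg.n_features
    n_t1 = int(round(cfg.frac_de_t1 * n))
    n_t2 = int(round(cfg.frac_de_t2 * n))
    if n_t1 + n_t2 > n:
        raise ValueError("planted DE count exceeds n_features")

    feature_ids = [f"tx_{i:05d}" for i in range(n)]
    perm = rng.permutation(n)
    t1_idx = perm[:n_t1]
    t2_idx = perm[n_t1 : n_t1 + n_t2]

    # relative baseline abundance per feature
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    base /= base.sum()

    # per-stage multiplier, default flat
    mult = np.ones((n, len(design.stage_order)))
    truth = SimTruth(de_features={"T1": {}, "T2": {}})

    def plant(indices, archetype_pool, transition_slot):
        for i in indices:
            arch = int(rng.choice(archetype_pool))
            d1, d2, scale = ARCHETYPES[arch]
            fold = float(rng.uniform(*cfg.de_fold_range)) * scale
            fid = feature_ids[i]
            truth.archetype_of[fid] = arch
            if d1 != 0:
                mult[i, 1] = mult[i, 0] * fold ** d1
            else:
                mult[i, 1] = mult[i, 0]
            if d2 != 0:
                mult[i, 2] = mult[i, 1] * fold ** d2
            else:
                mult[i, 2] = mult[i, 1]
            if transition_slot == "T1":
                truth.de_features["T1"][fid] = ("up" if d1 > 0 else "down", fold)
            else:
                truth.de_features["T2"][fid] = ("up" if d2 > 0 else "down", fold)

    plant(t1_idx, _T1_ONLY, "T1")
    plant(t2_idx, _T2_ONLY, "T2")

    # per-library size factors, log-normal around lib_size_mean
    lib_sizes = cfg.lib_size_mean * rng.lognormal(0.0, 0.1, size=len(design.samples))

    counts = np.zeros((n, len(design.samples)), dtype=np.int64)
    for j, sample in enumerate(design.samples):
        stage_idx = design.stage_order.index(design.stage_of[sample])
        mu = base * mult[:, stage_idx]
        mu = mu / mu.sum() * lib_sizes[j]
        counts[:, j] = _nb_sample(rng, mu, cfg.nb_dispersion)

    if cfg.frac_zero > 0:
        mask = rng.random(counts.shape) < cfg.frac_zero
        counts[mask] = 0

    frame = pd.DataFrame(counts, index=feature_ids, columns=list(design.samples))
    return CountMatrix(frame, design), truth


def simulate_go_annotation(truth: SimTruth, cfg: SimConfig) -> dict[str, set[str]]:
    """Assign GO terms: base rates everywhere, boosted rates for planted
    (archetype, term) pairs within that archetype's features."""
    rng = np.random.default_rng(cfg.seed + _OFF_GO)
    for _, _, factor in cfg.planted_enriched:
        if factor <= 0:
            raise ValueError("enrichment factor must be > 0")
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    boost: dict[tuple[int, str], float] = {
        (arch, term): factor for arch, term, factor in cfg.planted_enriched
    }
    features = [f"tx_{i:05d}" for i in range(cfg.n_features)]
    annotation: dict[str, set[str]] = {}
    for fid in features:
        arch = truth.archetype_of.get(fid)
        assigned = set()
        for term in terms:
            rate = cfg.go_base_rate
            if arch is not None and (arch, term) in boost:
                rate = min(1.0, rate * boost[(arch, term)])
            if rng.random() < rate:
                assigned.add(term)
        if assigned:
            annotation[fid] = assigned
    truth.enriched_pairs = [(a, t) for a, t, _ in cfg.planted_enriched]
    return annotation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def simulate_srna_libraries(
    cfg: SimConfig, truth: SimTruth | None = None
) -> tuple[dict[str, list[str]], SimTruth, list[tuple[str, str]]]:
    """Generate per-library sRNA reads, truth labels and a mature reference.

    Lengths follow ``srna_len_weights``; per-library counts are NB-draws
    whose means follow a flat/up/down stage trend per distinct sequence;
    ``n_planted_mirnas`` sequences are copied verbatim into the mature
    miRNA reference (alongside random decoys).
    """
    rng = np.random.default_rng(cfg.seed + _OFF_SRNA)
    truth = truth or SimTruth()
    lengths = sorted(cfg.srna_len_weights)
    if lengths and (lengths[0] < 15 or lengths[-1] > 28):
        raise ValueError("srna_len_weights keys must lie within [15, 28]")
    weights = np.array([cfg.srna_len_weights[k] for k in lengths], dtype=float)
    weights /= weights.sum()

    seqs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(seqs) < cfg.srna_n_distinct and attempts < cfg.srna_n_distinct * 20:
        attempts += 1
        length = int(rng.choice(lengths, p=weights))
        s = _random_seq(rng, length)
        if s not in seen:
            seen.add(s)
            seqs.append(s)

    design = cfg.design()
    n = len(seqs)
    # stage trend per sequence: 0 flat, +1 up, -1 down
    trend = np.zeros(n, dtype=int)
    r = rng.random(n)
    trend[r < cfg.srna_frac_trend] = 1
    trend[(r >= cfg.srna_frac_trend) & (r < 2 * cfg.srna_frac_trend)] = -1
    folds = rng.uniform(*cfg.de_fold_range, size=n)

    reads: dict[str, list[str]] = {}
    for sample in design.samples:
        stage_idx = design.stage_order.index(design.stage_of[sample])
        mu = cfg.srna_mean_count * np.power(folds, trend * stage_idx)
        counts = _nb_sample(rng, mu, cfg.nb_dispersion)
        lib_reads: list[str] = []
        for s, c in zip(seqs, counts):
            lib_reads.extend([s] * int(c))
        reads[sample] = lib_reads

    n_mirna = min(cfg.n_planted_mirnas, n)
    planted_idx = rng.choice(n, size=n_mirna, replace=False)
    mature: list[tuple[str, str]] = []
    for k, i in enumerate(sorted(planted_idx)):
        mid = f"sim-miR{k + 1}"
        mature.append((mid, seqs[i]))
        truth.mirna_srnas[seqs[i]] = mid
    for k in range(n_mirna):  # decoys absent from the libraries
        decoy = _random_seq(rng, 21)
        if decoy not in seen:
            mature.append((f"sim-decoy{k + 1}", decoy))
    return reads, truth, mature


def simulate_target_pairs(
    cfg: SimConfig,
    srna_expr: ExpressionMatrix,
    tx_expr: ExpressionMatrix,
    truth: SimTruth | None = None,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Build a candidate pair table with a planted anticorrelated fraction.

    Planted pairs are drawn from (sRNA, transcript) combinations whose
    stage-mean Pearson correlation is <= -0.95; the rest pair random
    profiles. Errors if more pairs are requested than combinations exist.
    """
    rng = np.random.default_rng(cfg.seed + _OFF_PAIRS)
    truth = truth or SimTruth()
    if list(srna_expr.design.stage_order) != list(tx_expr.design.stage_order):
        raise ValueError("stage labels of the two matrices disagree")
    s_means = srna_expr.stage_means()
    t_means = tx_expr.stage_means()
    n_pairs = cfg.n_target_pairs
    total_combos = len(s_means) * len(t_means)
    if n_pairs > total_combos:
        raise ValueError("n_target_pairs exceeds available combinations")
    n_anti = int(round(cfg.frac_anticorrelated_pairs * n_pairs))

    def z(frame: pd.DataFrame) -> np.ndarray:
        v = frame.to_numpy(dtype=float)
        vc = v - v.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(vc, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = vc / norm
        return np.nan_to_num(out)

    sz, tz = z(s_means), z(t_means)
    corr = sz @ tz.T  # (srna, transcript) stage-mean Pearson

    anti_i, anti_j = np.nonzero(corr <= -0.95)
    if len(anti_i) < n_anti:
        raise ValueError(
            f"only {len(anti_i)} anticorrelated combinations available, "
            f"need {n_anti}"
        )
    pick = rng.choice(len(anti_i), size=n_anti, replace=False)
    pairs: list[tuple[str, str]] = []
    used: set[tuple[int, int]] = set()
    for k in pick:
        i, j = int(anti_i[k]), int(anti_j[k])
        used.add((i, j))
        pair = (str(s_means.index[i]), str(t_means.index[j]))
        pairs.append(pair)
        truth.anticorrelated_pairs.append(pair)

    while len(pairs) < n_pairs:
        i = int(rng.integers(len(s_means)))
        j = int(rng.integers(len(t_means)))
        if (i, j) in used:
            continue
        used.add((i, j))
        pairs.append((str(s_means.index[i]), str(t_means.index[j])))
    return pairs, truth
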