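"""Contig-to-transcript restructuring via best cDNA hits.

Contigs sharing a best cDNA hit are clustered into a single transcript;
counts and GO annotations are aggregated to the transcript level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from stagewise.io import ContigHit
from stagewise.matrix import CountMatrix

DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class TranscriptCluster:
    transcript_id: str
    member_contigs: frozenset[str]
    source: str  # "known-cDNA" | "novel"
    cdna_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.member_contigs:
            raise ValueError("cluster must have at least one member contig")
        if (self.source == "known-cDNA") != (self.cdna_id is not None):
            raise ValueError("cdna_id present iff source is known-cDNA")


def assign_best_hit(
    hits: Iterable[ContigHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[str, str]:
    """Best surviving hit per contig: highest bitscore, then lowest evalue,
    then lexicographically smallest cdna_id. Contigs whose hits all exceed
    *max_evalue* are absent from the result."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    best: dict[str, ContigHit] = {}
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        cur = best.get(hit.contig_id)
        if cur is None:
            best[hit.contig_id] = hit
            continue
        key_new = (-hit.bitscore, hit.evalue, hit.cdna_id)
        key_cur = (-cur.bitscore, cur.evalue, cur.cdna_id)
        if key_new < key_cur:
            best[hit.contig_id] = hit
    return {contig: hit.cdna_id for contig, hit in best.items()}


def build_transcripts(
    assignment: dict[str, str], all_contigs: Iterable[str]
) -> list[TranscriptCluster]:
    """One cluster per distinct cDNA; unassigned contigs become novel
    singleton clusters. Clusters partition *all_contigs*."""
    contigs = list(all_contigs)
    if len(set(contigs)) != len(contigs):
        seen, dups = set(), []
        for c in contigs:
            if c in seen:
                dups.append(c)
            seen.add(c)
        raise ValueError(f"duplicate contigs: {dups[:5]}")
    unknown = set(assignment) - set(contigs)
    if unknown:
        raise ValueError(f"assignment references unknown contigs: {sorted(unknown)[:5]}")

    by_cdna: dict[str, list[str]] = {}
    for contig in contigs:
        cdna = assignment.get(contig)
        if cdna is not None:
            by_cdna.setdefault(cdna, []).append(contig)

    clusters: list[TranscriptCluster] = []
    for cdna in sorted(by_cdna):
        clusters.append(
            TranscriptCluster(
                transcript_id=cdna,
                member_contigs=frozenset(by_cdna[cdna]),
                source="known-cDNA",
                cdna_id=cdna,
            )
        )
    for contig in contigs:
        if contig not in assignment:
            clusters.append(
                TranscriptCluster(
                    transcript_id=f"novel_{contig}",
                    member_contigs=frozenset([contig]),
                    source="novel",
                )
            )
    return clusters


def aggregate_counts(
    contig_counts: CountMatrix, clusters: list[TranscriptCluster]
) -> CountMatrix:
    """Sum member contig counts per sample. Per-sample totals are conserved
    when the clusters partition the matrix features."""
    index = contig_counts.values.index
    rows = {}
    for cluster in clusters:
        missing = [c for c in cluster.member_contigs if c not in index]
        if missing:
            raise ValueError(
                f"cluster {cluster.transcript_id!r}: contig {missing[0]!r} "
                "missing from count matrix"
            )
        rows[cluster.transcript_id] = contig_counts.values.loc[
            sorted(cluster.member_contigs)
        ].sum(axis=0)
    out = pd.DataFrame(rows).T
    out = out.loc[[c.transcript_id for c in clusters]]
    return CountMatrix(out.astype("int64"), contig_counts.design)


def merge_go_terms(
    clusters: list[TranscriptCluster], contig_go: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Transcript term set = union over member contigs; transcripts with no
    annotated member are absent from the result."""
    merged: dict[str, set[str]] = {}
    for cluster in clusters:
        terms: set[str] = set()
        for contig in cluster.member_contigs:
            terms |= contig_go.get(contig, set())
        if terms:
            merged[cluster.transcript_id] = terms
    return merged
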