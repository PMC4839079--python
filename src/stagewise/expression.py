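"""Expressed-feature calling per stage, Venn partitioning and percentages."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from stagewise.matrix import ExpressionMatrix


@dataclass
class ExpressedSets:
    """Per-stage sets of features expressed in all replicates of the stage."""

    stage_sets: dict[str, set[str]]
    universe_size: int

    @property
    def expressed_union(self) -> set[str]:
        union: set[str] = set()
        for s in self.stage_sets.values():
            union |= s
        return union


def call_expressed(expr: ExpressionMatrix, threshold: float = 1.0) -> ExpressedSets:
    """A feature is expressed in a stage iff its value is >= *threshold* in
    ALL replicates of that stage (inclusive boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    expr.design.require_replicates(1)
    stage_sets: dict[str, set[str]] = {}
    for stage in expr.design.stage_order:
        cols = expr.design.samples_of(stage)
        if not cols:
            raise ValueError(f"stage {stage!r} has no replicates")
        mask = (expr.values[cols] >= threshold).all(axis=1)
        stage_sets[stage] = set(expr.values.index[mask])
    return ExpressedSets(stage_sets=stage_sets, universe_size=len(expr.values))


VENN_REGIONS = (
    "s1_only",
    "s2_only",
    "s3_only",
    "s1_s2_only",
    "s1_s3_only",
    "s2_s3_only",
    "core",
)


def venn_partition(sets: ExpressedSets) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a 3-set Venn diagram.

    Region counts sum to the size of the union.
    """
    if len(sets.stage_sets) != 3:
        raise ValueError(f"need exactly 3 stage sets, got {len(sets.stage_sets)}")
    s1, s2, s3 = (sets.stage_sets[k] for k in sets.stage_sets)
    return {
        "s1_only": len(s1 - s2 - s3),
        "s2_only": len(s2 - s1 - s3),
        "s3_only": len(s3 - s1 - s2),
        "s1_s2_only": len((s1 & s2) - s3),
        "s1_s3_only": len((s1 & s3) - s2),
        "s2_s3_only": len((s2 & s3) - s1),
        "core": len(s1 & s2 & s3),
    }


def percent(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total rounded half-away-from-zero to *decimals* places."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))
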