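"""Filter-cascade differential-expression caller.

A feature is DE for a transition iff the higher stage mean reaches the
minimum expression, the fold change reaches the minimum fold, the replicate
coefficient of variation stays within bounds in both stages, and the
equal-variance two-sample t-test survives Benjamini-Hochberg FDR control
over the filter-passing set of that transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from stagewise.config import PipelineConfig
from stagewise.matrix import ExpressionMatrix


@dataclass
class DECall:
    """Per-feature differential-expression record for one transition."""

    feature_id: str
    transition: str
    mean_low: float
    mean_high: float
    fold_change: float  # max/min, may be inf
    direction: str  # "up" | "down"
    cv_low: float
    cv_high: float
    p_value: float  # nan when filters not passed (test not run)
    q_significant: bool
    passed_filters: bool

    @property
    def is_de(self) -> bool:
        return self.passed_filters and self.q_significant


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Fold = max/min (inf if min is 0); direction 'up' iff the later-stage
    mean (*mean_b*) is strictly greater. Equal means are 'down' by
    convention (fold 1 can never pass the filter)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if mean_a == 0 and mean_b == 0:
        raise ValueError("fold change undefined for two zero means")
    lo, hi = min(mean_a, mean_b), max(mean_a, mean_b)
    fold = math.inf if lo == 0 else hi / lo
    direction = "up" if mean_b > mean_a else "down"
    return fold, direction


def stage_cv(replicates) -> float:
    """Sample SD (n-1) divided by the mean; all-zero replicates give 0."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 replicates for a CV")
    mean = arr.mean()
    if mean == 0:
        if np.all(arr == 0):
            return 0.0
        raise ValueError("zero mean with nonzero replicates")
    return float(arr.std(ddof=1) / mean)


def student_t_p(group_a, group_b) -> float:
    """Two-sided pooled-variance t-test p-value (df = n_a + n_b - 2).

    Degenerate conventions: both groups zero-variance and equal means give
    p = 1; both zero-variance with unequal means give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level *alpha*."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = alpha * (np.arange(1, m + 1) / m)
    under = np.nonzero(sorted_p <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if under.size:
        k = under.max()
        reject[order[: k + 1]] = True
    return reject


def call_de(
    expr: ExpressionMatrix,
    transition: tuple[str, str],
    cfg: PipelineConfig | None = None,
) -> list[DECall]:
    """Run the full filter cascade plus t-test/FDR for one transition.

    The t-test is computed only for filter-passing features and BH is
    applied across exactly that set.
    """
    cfg = cfg or PipelineConfig()
    stage_a, stage_b = transition
    design = expr.design
    label = design.transition_label(transition)
    cols_a = design.samples_of(stage_a)
    cols_b = design.samples_of(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each transition stage needs >= 2 replicates")

    vals_a = expr.values[cols_a].to_numpy(dtype=float)
    vals_b = expr.values[cols_b].to_numpy(dtype=float)

    calls: list[DECall] = []
    for i, feature in enumerate(expr.values.index):
        a, b = vals_a[i], vals_b[i]
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a == 0 and mean_b == 0:
            continue  # fold change undefined; feature excluded
        fold, direction = fold_change(mean_a, mean_b)
        cv_a, cv_b = stage_cv(a), stage_cv(b)
        lo, hi = min(mean_a, mean_b), max(mean_a, mean_b)
        passed = (
            hi >= cfg.de_min_rpmqn
            and fold >= cfg.de_min_fold
            and cv_a <= cfg.de_max_cv
            and cv_b <= cfg.de_max_cv
        )
        p = student_t_p(a, b) if passed else math.nan
        calls.append(
            DECall(
                feature_id=str(feature),
                transition=label,
                mean_low=lo,
                mean_high=hi,
                fold_change=fold,
                direction=direction,
                cv_low=cv_a if mean_a <= mean_b else cv_b,
                cv_high=cv_b if mean_a <= mean_b else cv_a,
                p_value=p,
                q_significant=False,
                passed_filters=passed,
            )
        )

    tested = [c for c in calls if c.passed_filters]
    if tested:
        reject = bh_fdr([c.p_value for c in tested], cfg.de_fdr_alpha)
        for call, r in zip(tested, reject):
            call.q_significant = bool(r)
    return calls


def de_summary(calls: list[DECall]) -> dict:
    """Counts and up/down split of DE features for reporting."""
    from stagewise.expression import percent

    de = [c for c in calls if c.is_de]
    n_up = sum(1 for c in de if c.direction == "up")
    n_down = len(de) - n_up
    out = {
        "n_tested": sum(1 for c in calls if c.passed_filters),
        "n_de": len(de),
        "n_up": n_up,
        "n_down": n_down,
    }
    if de:
        out["pct_up"] = percent(n_up, len(de))
        out["pct_down"] = percent(n_down, len(de))
    return out
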