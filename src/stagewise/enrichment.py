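"""Bootstrap GO-term over-representation testing with FDR control.

The null distribution is built by drawing random feature sets of the same
size from the annotated universe (with replacement by default — a literal
bootstrap — or without replacement behind a flag) and counting how often a
random set carries the term at least as many times as observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from stagewise.config import PipelineConfig
from stagewise.diffexpr import bh_fdr


@dataclass
class EnrichmentResult:
    set_label: str
    go_term: str
    observed_count: int
    set_size: int
    universe_frequency: float
    p_value: float
    q_significant: bool


def binomial_tail(observed: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= observed)."""
    if not 0 <= observed <= n:
        raise ValueError("observed must lie in [0, n]")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, p))


def bootstrap_p(
    observed: int,
    set_size: int,
    term_frequency: float,
    runs: int,
    seed: int | np.random.Generator = 0,
    *,
    universe_size: int | None = None,
    with_replacement: bool = True,
) -> float:
    """Monte-Carlo p-value for observing >= *observed* term carriers.

    Each run draws *set_size* features from the annotated universe (with
    replacement by default) and counts term carriers; the count of a run is
    therefore Binomial(set_size, term_frequency), which is sampled directly.
    p = (1 + #{run count >= observed}) / (runs + 1), never exactly 0.

    The without-replacement mode needs *universe_size* and draws
    hypergeometric run counts instead.
    """
    if observed > set_size:
        raise ValueError("observed exceeds set size")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if not 0 <= term_frequency <= 1:
        raise ValueError("term_frequency must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if observed == 0:
        return 1.0
    if with_replacement:
        counts = rng.binomial(set_size, term_frequency, size=runs)
    else:
        if universe_size is None:
            raise ValueError("universe_size required without replacement")
        n_term = int(round(term_frequency * universe_size))
        counts = rng.hypergeometric(
            n_term, universe_size - n_term, set_size, size=runs
        )
    hits = int(np.count_nonzero(counts >= observed))
    return (1 + hits) / (runs + 1)


def enrich_set(
    features: set[str],
    annotation: dict[str, set[str]],
    universe: set[str] | None = None,
    cfg: PipelineConfig | None = None,
    *,
    set_label: str = "set",
    with_replacement: bool = True,
    runs: int | None = None,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Test every term carried by >= ``cfg.enrich_min_count`` set members.

    The universe defaults to all annotated features; term frequencies are
    computed over it. BH step-up is applied across the surviving terms of
    this one set; results are sorted by p-value.
    """
    cfg = cfg or PipelineConfig()
    annotated = {f for f, terms in annotation.items() if terms}
    if universe is None:
        universe = annotated
    else:
        universe = set(universe) & annotated
    if not universe:
        raise ValueError("annotated universe is empty")
    if not features <= universe:
        features = features & universe

    universe_term_counts: dict[str, int] = {}
    for f in universe:
        for t in annotation.get(f, ()):
            universe_term_counts[t] = universe_term_counts.get(t, 0) + 1

    set_term_counts: dict[str, int] = {}
    for f in features:
        for t in annotation.get(f, ()):
            set_term_counts[t] = set_term_counts.get(t, 0) + 1

    n_runs = runs if runs is not None else cfg.boot_runs
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    set_size = len(features)
    n_universe = len(universe)

    results: list[EnrichmentResult] = []
    for term in sorted(set_term_counts):
        observed = set_term_counts[term]
        if observed < cfg.enrich_min_count:
            continue
        freq = universe_term_counts[term] / n_universe
        p = bootstrap_p(
            observed,
            set_size,
            freq,
            n_runs,
            rng,
            universe_size=n_universe,
            with_replacement=with_replacement,
        )
        results.append(
            EnrichmentResult(
                set_label=set_label,
                go_term=term,
                observed_count=observed,
                set_size=set_size,
                universe_frequency=freq,
                p_value=p,
                q_significant=False,
            )
        )
    if results:
        reject = bh_fdr([r.p_value for r in results], cfg.enrich_fdr_alpha)
        for r, rej in zip(results, reject):
            r.q_significant = bool(rej)
    results.sort(key=lambda r: (r.p_value, r.go_term))
    return results
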