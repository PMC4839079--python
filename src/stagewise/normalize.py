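"""Zero-preserving quantile normalization scaled to rpmqn.

Columns are forced onto a common reference distribution (positionwise mean
of the sorted columns) with average-tie handling; entries whose raw count
is zero are reset to zero so that no expression is allocated to features
not observed in a sample; finally every column is scaled to one million
quantile-normalized reads (rpmqn).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stagewise.matrix import CountMatrix, ExpressionMatrix


def quantile_normalize_zero_preserving(counts: CountMatrix) -> pd.DataFrame:
    """Quantile-normalize columns, then reset raw-zero entries to zero.

    Ties within a column receive the mean reference value over their tied
    rank positions. Requires at least two samples.
    """
    raw = counts.values.to_numpy(dtype=float)
    n_features, n_samples = raw.shape
    if n_features < 1:
        raise ValueError("matrix has no features")
    if n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")

    reference = np.sort(raw, axis=0).mean(axis=1)

    out = np.empty_like(raw)
    for j in range(n_samples):
        col = raw[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # mean reference value over each run of tied sorted positions
        assigned = np.empty(n_features)
        start = 0
        while start < n_features:
            stop = start
            while stop + 1 < n_features and sorted_vals[stop + 1] == sorted_vals[start]:
                stop += 1
            assigned[start : stop + 1] = reference[start : stop + 1].mean()
            start = stop + 1
        out[order, j] = assigned

    out[raw == 0] = 0.0
    return pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns)


def scale_rpmqn(normalized: pd.DataFrame, design) -> ExpressionMatrix:
    """Scale every column to sum to 1e6. All-zero columns are an error."""
    sums = normalized.sum(axis=0)
    zero_cols = sums[sums <= 0]
    if len(zero_cols) > 0:
        raise ValueError(f"all-zero sample column: {zero_cols.index[0]!r}")
    scaled = normalized * (1_000_000.0 / sums)
    return ExpressionMatrix(scaled, design)


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Full pipeline: zero-preserving quantile normalization then rpmqn."""
    return scale_rpmqn(quantile_normalize_zero_preserving(counts), counts.design)
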