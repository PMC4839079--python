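"""Expression-profile analysis: z-scored stage profiles, k-means clustering
with centered-correlation dissimilarity, PCA grouping of replicates, and
Pearson/complete-linkage replicate dendrograms."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from stagewise.matrix import ExpressionMatrix


@dataclass
class ProfileMatrix:
    """Per-feature z-normalized stage-mean profiles.

    Features whose stage means have zero variance cannot be z-scored and are
    listed in ``excluded`` instead.
    """

    z_values: pd.DataFrame  # features x stages
    stage_order: tuple[str, ...]
    excluded: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.z_values.index)


def zscore_profiles(expr: ExpressionMatrix, features=None) -> ProfileMatrix:
    """Stage means per feature, centered and scaled by sample SD (n-1)."""
    if features is not None:
        features = list(features)
        if not features:
            raise ValueError("empty feature set")
        expr = expr.subset(features)
    means = expr.stage_means()
    if means.empty:
        raise ValueError("empty feature set")
    sd = means.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = list(means.index[~keep])
    kept = means.loc[keep]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ProfileMatrix(
        z_values=z, stage_order=tuple(expr.design.stage_order), excluded=excluded
    )


def _centered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation after centering; zero-variance vectors give 0."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        return 0.0
    return float((xc @ yc) / (nx * ny))


def _dissimilarity_to_centroids(data: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """d(x, c) = 1 - Pearson(x, c) for every (point, centroid) pair."""
    dc = data - data.mean(axis=1, keepdims=True)
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    dn = np.linalg.norm(dc, axis=1)
    cn = np.linalg.norm(cc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (dc @ cc.T) / np.outer(dn, cn)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    return 1.0 - corr


@dataclass
class KMeansResult:
    assignments: pd.Series  # feature -> cluster index
    centroids: pd.DataFrame  # cluster x stage
    total_dissimilarity: float
    objective_trace: list[float]  # per-iteration objective of the best run
    effective_k: int


def _kmeans_single(
    data: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = data.shape[0]
    centroids = data[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for _ in range(max_iter):
        dist = _dissimilarity_to_centroids(data, centroids)
        new_labels = dist.argmin(axis=1)
        # re-seed empty clusters from the worst-fitting point
        for c in range(k):
            if not np.any(new_labels == c):
                worst = dist[np.arange(n), new_labels].argmax()
                centroids[c] = data[worst]
                dist = _dissimilarity_to_centroids(data, centroids)
                new_labels = dist.argmin(axis=1)
        trace.append(float(dist[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = data[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    dist = _dissimilarity_to_centroids(data, centroids)
    objective = float(dist[np.arange(n), labels].sum())
    return labels, centroids, objective, trace


def kmeans_centered_correlation(
    profiles: ProfileMatrix, k: int, restarts: int = 20, seed: int = 0
) -> KMeansResult:
    """Lloyd k-means with d = 1 - Pearson; best of *restarts* seeded runs.

    All-identical profiles with k > 1 degenerate to one effective cluster
    (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = profiles.z_values.to_numpy(dtype=float)
    n = data.shape[0]
    if n < k:
        raise ValueError(f"{n} profiles but k={k}")
    if n > 1 and np.allclose(data, data[0]) and k > 1:
        warnings.warn("all profiles identical; returning a single cluster")
        k = 1
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        run = _kmeans_single(data, k, rng)
        if best is None or run[2] < best[2]:
            best = run
    labels, centroids, objective, trace = best
    effective = len(np.unique(labels))
    return KMeansResult(
        assignments=pd.Series(labels, index=profiles.z_values.index, name="cluster"),
        centroids=pd.DataFrame(
            centroids, columns=list(profiles.stage_order)
        ),
        total_dissimilarity=objective,
        objective_trace=trace,
        effective_k=effective,
    )


def pca_variance(
    expr_z: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a sample x feature matrix via SVD of the column-centered data.

    Returns per-sample scores and variance-explained fractions
    (non-increasing, summing to <= 1). Component signs are fixed by making
    each component's largest-magnitude loading positive.
    """
    x = expr_z.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples for PCA")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = rank
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(n_components):
        j = np.abs(vt[i]).argmax()
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :n_components] * s[:n_components]
    score_df = pd.DataFrame(
        scores,
        index=expr_z.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return score_df, fractions[:n_components]


def replicate_distance_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise sample distance 1 - Pearson over feature value vectors."""
    vals = expr.values
    sds = vals.std(axis=0, ddof=1)
    zero = sds[sds == 0]
    if len(zero) > 0:
        raise ValueError(
            f"zero-variance sample {zero.index[0]!r}: correlation undefined"
        )
    corr = vals.corr(method="pearson")
    return 1.0 - corr


def replicate_dendrogram(expr: ExpressionMatrix) -> str:
    """Complete-linkage tree over samples in Newick format (with heights).

    Distance = 1 - Pearson correlation of the sample value vectors; leaf
    order ties break by sample-ID order (samples are presented in design
    order to the deterministic linkage).
    """
    dist = replicate_distance_matrix(expr)
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.complete(condensed)
    tree = hierarchy.to_tree(linkage)
    labels = list(dist.columns)

    def newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"
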