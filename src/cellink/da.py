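"""Multiscale kNN differential abundance between two conditions.

For every cell, the fraction of its k nearest neighbors (in a PCA
embedding) belonging to condition A is recorded across a grid of
neighborhood sizes k; an L2-regularized logistic model then predicts the
cell's condition from this multiscale score vector, and the DA measure is
the predicted probability rescaled to [-1, 1]. Cells beyond fixed
symmetric thresholds (default +/-0.8) form the differentially abundant
set, which is partitioned into subpopulations by community detection on a
kNN graph restricted to those cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DaConfig",
    "DaResult",
    "knn_neighbor_order",
    "knn_score_vector",
    "scores_from_order",
    "da_measure",
    "select_da_cells",
    "cluster_da_cells",
    "run_da",
]

#: the study's default neighborhood grid and the reduced preset used for
#: the larger replication cohorts
DEFAULT_K_GRID = tuple(range(100, 4001, 500))
ALT_K_GRID = tuple(range(100, 1001, 100))


@dataclass
class DaConfig:
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    measure_thresholds: tuple[float, float] = (-0.8, 0.8)
    n_pcs: int = 40
    cluster_resolution: float = 0.01
    cluster_knn: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.measure_thresholds
        if not (-1 < lo < hi < 1):
            raise ValueError("thresholds must satisfy -1 < lower < upper < 1")
        if min(self.k_grid) < 1:
            raise ValueError("k values must be positive")


@dataclass
class DaResult:
    scores: np.ndarray = field(repr=False)
    measure: np.ndarray = field(repr=False)
    da_cells: np.ndarray = field(repr=False)
    labels: pd.Series | None = field(default=None, repr=False)
    k_grid: tuple[int, ...] = ()


def knn_neighbor_order(embedding: np.ndarray, block: int = 2048) -> np.ndarray:
    """Neighbor indices of every cell sorted by (Euclidean distance, index),
    self excluded. Returns an (n, n-1) int array.

    Exact and deterministic: distance ties are broken by cell index via a
    stable argsort. Quadratic in n; intended for cohort-scale embeddings
    (tens of thousands of cells at most).
    """
    X = np.asarray(embedding, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("embedding must be finite")
    n = X.shape[0]
    sq = (X**2).sum(axis=1)
    out = np.empty((n, n - 1), dtype=np.int32)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * X[start:stop] @ X.T
        np.maximum(d2, 0.0, out=d2)
        order = np.argsort(np.round(d2, 12), axis=1, kind="stable")
        for i in range(start, stop):
            row = order[i - start]
            out[i] = row[row != i]
    return out


def scores_from_order(
    order: np.ndarray, condition: np.ndarray, cond_a, k_grid
) -> np.ndarray:
    """Multiscale score vectors from a precomputed neighbor ordering.

    Entry (cell, k) is the fraction of the cell's k nearest neighbors with
    condition ``cond_a``. Separating this from the distance computation
    lets permutation nulls reuse the neighbor ordering.
    """
    n = order.shape[0]
    k_grid = tuple(k_grid)
    if max(k_grid) >= n:
        raise ValueError(f"k={max(k_grid)} must be below the number of cells ({n})")
    is_a = (np.asarray(condition) == cond_a).astype(np.float64)
    counts = np.cumsum(is_a[order], axis=1)
    ks = np.asarray(k_grid)
    return counts[:, ks - 1] / ks


def knn_score_vector(
    embedding: np.ndarray,
    condition: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    cond_a=None,
) -> np.ndarray:
    """Fraction of condition-A cells among each cell's k nearest neighbors,
    for every k in the grid (self excluded, ties by cell index)."""
    condition = np.asarray(condition)
    labels = np.unique(condition)
    if len(labels) < 2:
        raise ValueError("both conditions must be present")
    if cond_a is None:
        cond_a = labels[0]
    order = knn_neighbor_order(embedding)
    return scores_from_order(order, condition, cond_a, k_grid)


def da_measure(
    scores: np.ndarray,
    condition: np.ndarray,
    cond_a=None,
    seed: int = 0,
    C: float = 100.0,
) -> np.ndarray:
    """DA measure in [-1, 1] from the multiscale score vectors.

    An L2-regularized logistic model predicts the condition from the score
    vector; the measure is 2 * P(condition A) - 1, positive for cells in
    neighborhoods enriched for condition A. The default regularization is
    weak (C=100): with at most a dozen bounded features and thousands of
    cells, near-MLE fitting keeps the predicted probabilities calibrated
    instead of shrunk toward the base rate, which matters because the
    selection thresholds are fixed absolute values.
    """
    condition = np.asarray(condition)
    labels = np.unique(condition)
    if len(labels) < 2:
        raise ValueError("both conditions must be present")
    if cond_a is None:
        cond_a = labels[0]
    y = (condition == cond_a).astype(int)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(scores, y)
    q = clf.predict_proba(scores)[:, list(clf.classes_).index(1)]
    return 2.0 * q - 1.0


def select_da_cells(
    measure: np.ndarray, thresholds: tuple[float, float] = (-0.8, 0.8)
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of cells beyond the thresholds and their direction sign
    (+1: enriched in condition A, -1: enriched in the other condition)."""
    lo, hi = thresholds
    measure = np.asarray(measure)
    sel = np.flatnonzero((measure >= hi) | (measure <= lo))
    return sel, np.sign(measure[sel]).astype(int)


def cluster_da_cells(
    embedding: np.ndarray,
    resolution: float = 0.01,
    k: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Partition DA cells into subpopulations.

    Community detection (Leiden, the seeded successor of Louvain, with the
    RB resolution parameter) on a symmetrized kNN graph of the DA cells;
    singleton communities are merged into the community with the nearest
    centroid. Fewer than two cells yield a single trivial label.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    import igraph
    import leidenalg

    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)

    # merge singletons into the nearest community by centroid distance
    sizes = pd.Series(labels).value_counts()
    singles = sizes[sizes == 1].index
    if len(singles) and len(sizes) > len(singles):
        keep = [c for c in sizes.index if c not in set(singles)]
        centroids = {c: X[labels == c].mean(axis=0) for c in keep}
        for c in singles:
            i = int(np.flatnonzero(labels == c)[0])
            d = {cc: np.linalg.norm(X[i] - mu) for cc, mu in centroids.items()}
            labels[i] = min(d, key=d.get)
    # relabel 0..K-1 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    remap = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def run_da(
    embedding: np.ndarray,
    condition: np.ndarray,
    config: DaConfig | None = None,
    cond_a=None,
) -> DaResult:
    """Score, measure, select, and cluster in one call."""
    if config is None:
        config = DaConfig()
    n = len(condition)
    k_grid = tuple(k for k in config.k_grid if k < n)
    if not k_grid:
        raise ValueError("no k in the grid is below the number of cells")
    emb = np.asarray(embedding, float)[:, : config.n_pcs]
    scores = knn_score_vector(emb, condition, k_grid, cond_a=cond_a)
    measure = da_measure(scores, condition, cond_a=cond_a, seed=config.seed)
    sel, _ = select_da_cells(measure, config.measure_thresholds)
    labels = None
    if sel.size >= 2:
        lab = cluster_da_cells(
            emb[sel], resolution=config.cluster_resolution,
            k=config.cluster_knn, seed=config.seed,
        )
        labels = pd.Series(lab, index=sel, name="da_subpop")
    elif sel.size == 1:
        labels = pd.Series([0], index=sel, name="da_subpop")
    return DaResult(
        scores=scores, measure=measure, da_cells=sel, labels=labels, k_grid=k_grid
    )
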