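"""Sample-heterogeneity clustering of incomplete ddCt profiles.

Sample pairs are points in assay space; many coordinates are missing
because a reaction failed in one tissue or the other. Distances use the
pairwise-complete (masked) Euclidean convention: squared differences over
co-observed coordinates, rescaled by ``total_dims / n_co_observed`` so a
sparsely co-observed pair is not artificially close.

Partitioning is K-median — Lloyd-style alternation where each center
coordinate is the median of its members' observed values — which tolerates
absent cells naturally where a mean-based update would be biased by the
non-random missingness of weakly expressed assays. The number of clusters
is chosen with the elbow rule (maximal second difference of the cost
curve). Complete-linkage agglomeration on the same masked distance
provides heat-map row/column orders, and pairwise-complete Pearson
correlation compares two assays' deregulation profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "ClusterModel",
    "ElbowCurve",
    "masked_euclidean",
    "k_median",
    "elbow_select",
    "choose_elbow",
    "hierarchical_order",
    "pairwise_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterModel:
    """A fitted K-median partition of sample pairs.

    ``assignments`` maps each pair id to a label in 1..k; ``centers`` is a
    k x assay frame of per-coordinate medians (``NaN`` where a cluster has
    no observation for an assay); ``cost`` is the summed masked distance
    of every pair to its own center, minimal over the restarts performed.
    """

    k: int
    assignments: pd.Series
    centers: pd.DataFrame
    cost: float
    n_iter: int
    seed: int
    n_restarts: int


@dataclass(frozen=True)
class ElbowCurve:
    k_values: tuple[int, ...]
    costs: tuple[float, ...]
    chosen_k: int


def masked_euclidean(
    x: Sequence[float], y: Sequence[float], total_dims: Optional[int] = None
) -> float:
    """Euclidean distance over co-observed coordinates, rescaled to full
    dimensionality: ``sqrt((total_dims/|O|) * sum_{j in O} (x_j - y_j)^2)``.

    Raises ``ValueError`` when no coordinate is observed in both vectors.
    Reduces to the classical Euclidean distance on fully observed input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if total_dims is None:
        total_dims = x.size
    both = ~np.isnan(x) & ~np.isnan(y)
    n_obs = int(both.sum())
    if n_obs == 0:
        raise ValueError("incomparable vectors: no co-observed coordinate")
    ss = float(np.sum((x[both] - y[both]) ** 2))
    return float(np.sqrt(total_dims / n_obs * ss))


def _distances_to_centers(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Masked distances, points x centers; inf where incomparable."""
    n, d = X.shape
    k = centers.shape[0]
    out = np.empty((n, k))
    x_obs = ~np.isnan(X)
    for j in range(k):
        c = centers[j]
        both = x_obs & ~np.isnan(c)
        diff = np.where(both, X - c, 0.0)
        n_obs = both.sum(axis=1)
        ss = np.sum(diff * diff, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, j] = np.sqrt(d / n_obs * ss)
        out[n_obs == 0, j] = np.inf
    return out


def _median_centers(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    centers = np.full((k, X.shape[1]), np.nan)
    for j in range(k):
        members = X[labels == j]
        if members.size:
            with warnings.catch_warnings():
                # all-NaN columns legitimately yield a NaN center coordinate
                warnings.simplefilter("ignore", RuntimeWarning)
                centers[j] = np.nanmedian(members, axis=0)
    return centers


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = X.shape[0]
    init = rng.choice(n, size=k, replace=False)
    centers = X[init].copy()
    labels = np.full(n, -1)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = _distances_to_centers(X, centers)
        if np.isinf(dist.min(axis=1)).any():
            raise ValueError("a pair is incomparable with every center")
        new_labels = dist.argmin(axis=1)
        # re-seed empty clusters at the pair farthest from its center
        for j in range(k):
            if not (new_labels == j).any():
                own = dist[np.arange(n), new_labels]
                far = int(own.argmax())
                new_labels[far] = j
                logger.debug("re-seeded empty cluster %d at point %d", j, far)
        if (new_labels == labels).all():
            break
        labels = new_labels
        centers = _median_centers(X, labels, k)
    dist = _distances_to_centers(X, centers)
    cost = float(dist[np.arange(n), labels].sum())
    return labels, centers, cost, n_iter


def k_median(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> ClusterModel:
    """K-median partition of the pairs (columns) of an assay x pair matrix.

    Rows of the internal point matrix are sample pairs, coordinates are
    assays. Lloyd alternation (nearest center under the masked distance,
    per-coordinate median update over observed member values) runs to an
    assignment fixed point or ``max_iter``, restarted ``n_restarts`` times
    from distinct seeded initializations; the minimum-cost model wins.
    """
    X = matrix.to_numpy(dtype=float).T  # pairs x assays
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n} pairs, got k={k}")
    best = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        labels, centers, cost, n_iter = _lloyd(X, k, rng, max_iter)
        if best is None or cost < best[2]:
            best = (labels, centers, cost, n_iter)
    labels, centers, cost, n_iter = best
    assignments = pd.Series(labels + 1, index=matrix.columns, name="cluster")
    centers_df = pd.DataFrame(
        centers, index=pd.RangeIndex(1, k + 1, name="cluster"), columns=matrix.index
    )
    return ClusterModel(
        k=k,
        assignments=assignments,
        centers=centers_df,
        cost=cost,
        n_iter=n_iter,
        seed=seed,
        n_restarts=n_restarts,
    )


def elbow_select(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = range(1, 7),
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> ElbowCurve:
    """Choose k at the sharpest bend of the K-median cost curve.

    Runs :func:`k_median` for every k in ``k_range`` (>= 3 consecutive
    values starting at 1) and picks the interior k maximizing the second
    difference ``(cost[k-1] - cost[k]) - (cost[k] - cost[k+1])``, ties
    toward smaller k. A non-monotone cost curve is logged as a warning and
    the selection proceeds on the curve as computed.
    """
    ks = list(k_range)
    if len(ks) < 3 or ks[0] != 1 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be >= 3 consecutive values starting at 1")
    costs = [k_median(matrix, k, seed, n_restarts, max_iter).cost for k in ks]
    return ElbowCurve(
        k_values=tuple(ks), costs=tuple(costs), chosen_k=choose_elbow(ks, costs)
    )


def choose_elbow(k_values: Sequence[int], costs: Sequence[float]) -> int:
    """Interior k maximizing the cost curve's second difference.

    ``(cost[k-1] - cost[k]) - (cost[k] - cost[k+1])``, ties broken toward
    smaller k (``argmax`` keeps the first maximum).
    """
    ks = list(k_values)
    costs = list(costs)
    if len(ks) != len(costs) or len(ks) < 3:
        raise ValueError("need >= 3 (k, cost) points")
    if any(b > a for a, b in zip(costs, costs[1:])):
        logger.warning("k-median cost curve is not monotone non-increasing: %s", costs)
    second_diff = [
        (costs[i - 1] - costs[i]) - (costs[i] - costs[i + 1])
        for i in range(1, len(ks) - 1)
    ]
    return ks[1 + int(np.argmax(second_diff))]


def _condensed_masked(X: np.ndarray, names: Sequence, axis_name: str) -> np.ndarray:
    n, d = X.shape
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[idx] = masked_euclidean(X[i], X[j], d)
            except ValueError:
                raise ValueError(
                    f"incomparable {axis_name}s {names[i]!r} and {names[j]!r}: "
                    "no co-observed coordinate"
                ) from None
            idx += 1
    return out


def hierarchical_order(
    matrix: pd.DataFrame,
) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Two-way complete-linkage agglomeration for heat-map layout.

    Clusters rows (assays) and columns (pairs) independently on masked
    Euclidean distances. Returns ``(row_order, col_order, row_tree,
    col_tree)`` where the orders are id lists in dendrogram leaf order and
    the trees are scipy linkage matrices.
    """
    rows = matrix.to_numpy(dtype=float)
    row_tree = hierarchy.linkage(
        _condensed_masked(rows, list(matrix.index), "row"), method="complete"
    )
    col_tree = hierarchy.linkage(
        _condensed_masked(rows.T, list(matrix.columns), "column"), method="complete"
    )
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_tree)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_tree)]
    return row_order, col_order, row_tree, col_tree


def pairwise_correlation(
    matrix: pd.DataFrame, assay_a: str, assay_b: str
) -> tuple[float, int]:
    """Pairwise-complete Pearson correlation of two assays' ddCt profiles.

    Returns ``(r, n_used)`` over the pairs where both assays have a value.
    Raises with fewer than 3 complete pairs or zero variance on either side.
    """
    a = matrix.loc[assay_a].to_numpy(dtype=float)
    b = matrix.loc[assay_b].to_numpy(dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    n_used = int(both.sum())
    if n_used < 3:
        raise ValueError(
            f"only {n_used} complete pairs between {assay_a!r} and {assay_b!r}; need >= 3"
        )
    a, b = a[both], b[both]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the profiles")
    r = stats.pearsonr(a, b).statistic
    return float(r), n_used
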