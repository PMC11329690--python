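"""Hierarchical clustering on factor scores with k-means consolidation.

Persons are clustered in the Euclidean space of their retained MFA
dimensions.  The tree is Ward's minimum-variance linkage generalized to row
masses (survey weights): merging clusters A, B costs

    delta(A, B) = m_A * m_B / (m_A + m_B) * ||c_A - c_B||^2

which is exactly the increase in weighted within-cluster inertia, updated
by the Lance-Williams recurrence.  With integer weights the tree is
identical to the one on replicated unit-weight rows.  The number of
clusters is suggested from the relative drop in within-inertia (elbow on
the merge-height curve) but remains a user decision; the chosen partition
is consolidated by a few weighted k-means iterations started from the
hierarchical cluster centroids, which can only decrease within-inertia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._weights import as_weights
from .core_io import ValidationError

__all__ = ["LinkageTree", "KSuggestion", "ClusterSolution",
           "ward_tree", "cut_tree", "suggest_k", "cut_and_consolidate"]


@dataclass
class LinkageTree:
    """Weighted Ward merge history.

    ``merges`` has one row per merge: (id_a, id_b, height, mass) with
    scipy-style ids (original rows 0..n-1, then n+t for the cluster created
    at merge t) and height equal to the within-inertia increase of that
    merge.  Heights are non-decreasing.
    """

    merges: np.ndarray
    n_leaves: int
    index: pd.Index

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_nested_lists(self) -> list:
        """Tree as nested lists of person positions (JSON-exportable)."""
        nodes: dict[int, list | int] = {i: i for i in range(self.n_leaves)}
        for t, (a, b, _, _) in enumerate(self.merges):
            nodes[self.n_leaves + t] = [nodes.pop(int(a)), nodes.pop(int(b))]
        return nodes[self.n_leaves + len(self.merges) - 1]


def ward_tree(scores: pd.DataFrame | np.ndarray, weights=None) -> LinkageTree:
    """Agglomerative Ward linkage with row weights as masses.

    Ties are broken deterministically toward the pair with the lowest
    (row-major) slot indices.
    """
    if isinstance(scores, pd.DataFrame):
        index, X = scores.index, scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        index = pd.RangeIndex(len(X))
    n = len(X)
    if n < 2:
        raise ValidationError("need at least 2 persons to build a tree")
    if not np.all(np.isfinite(X)):
        raise ValidationError("scores contain NaN or inf")
    w = as_weights(weights, n).astype(float)

    sq = np.sum(X ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    mm = (w[:, None] * w[None, :]) / (w[:, None] + w[None, :])
    D = mm * d2
    np.fill_diagonal(D, np.inf)

    ids = np.arange(n)
    mass = w.copy()
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    for t in range(n - 1):
        flat = np.argmin(D)               # first occurrence = lowest (i, j)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        height = D[i, j]
        mi, mj = mass[i], mass[j]
        merges[t] = (ids[i], ids[j], height, mi + mj)

        k = active.copy()
        k[i] = k[j] = False
        denom = mi + mj + mass[k]
        D_new = ((mi + mass[k]) * D[i, k] + (mj + mass[k]) * D[j, k]
                 - mass[k] * height) / denom
        D[i, k] = D_new
        D[k, i] = D_new
        D[j, :] = np.inf
        D[:, j] = np.inf
        mass[i] = mi + mj
        ids[i] = n + t
        active[j] = False
    return LinkageTree(merges=merges, n_leaves=n, index=index)


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Labels 1..k from cutting the tree at k clusters.

    Cluster numbering is by the smallest original row position in each
    cluster, so it is deterministic.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    parent = np.arange(n + max(n - k, 0))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t in range(n - k):
        a, b, _, _ = tree.merges[t]
        new = n + t
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = np.array([find(i) for i in range(n)])
    _, first_pos = np.unique(roots, return_index=True)
    order = {roots[p]: rank + 1 for rank, p in enumerate(np.sort(first_pos))}
    return pd.Series([order[r] for r in roots], index=tree.index, name="cluster")


@dataclass
class KSuggestion:
    k: int
    gains: pd.Series      # between-inertia gain of moving from k-1 to k clusters
    ratios: pd.Series     # gain(k) / gain(k+1) over the candidate range
    weak_elbow: bool


def suggest_k(tree: LinkageTree, k_range=range(2, 9),
              weak_factor: float = 2.0) -> KSuggestion:
    """Advisory cluster count: the k maximizing gain(k)/gain(k+1).

    gain(k) is the drop in within-inertia when going from k-1 to k
    clusters (the height of the corresponding merge); a pronounced elbow
    makes that ratio large.  Structureless data also shows geometrically
    decaying gains, so the flat-curve flag is relative: the suggestion is a
    *weak elbow* when the best ratio does not exceed ``weak_factor`` times
    the median ratio over the candidate range.  The final k is the
    analyst's call either way.
    """
    n = tree.n_leaves
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    heights = tree.heights()
    gains = pd.Series({k: heights[n - k] for k in range(2, min(n, max(ks) + 2))})
    ratios = {}
    for k in ks:
        nxt = gains.get(k + 1, np.nan)
        ratios[k] = np.inf if nxt == 0 else gains[k] / nxt
    ratios = pd.Series(ratios)
    best = int(ratios.idxmax())
    finite = ratios[np.isfinite(ratios)]
    weak = bool(len(finite) == 0 or
                ratios.max() <= weak_factor * max(float(finite.median()), 1.0))
    return KSuggestion(k=best, gains=gains, ratios=ratios, weak_elbow=weak)


@dataclass
class ClusterSolution:
    """A cut-and-consolidated partition with its inertia decomposition."""

    tree: LinkageTree
    k: int
    labels_initial: pd.Series
    labels: pd.Series
    total_inertia: float
    within_inertia: float
    within_inertia_initial: float
    cluster_sizes: pd.Series       # weighted sizes (sum of weights per cluster)
    cluster_shares: pd.Series
    n_reassigned: int
    suggestion: KSuggestion | None = None
    centroids: pd.DataFrame = field(default=None)

    @property
    def between_inertia(self) -> float:
        return self.total_inertia - self.within_inertia


def _inertia(X: np.ndarray, w: np.ndarray, labels: np.ndarray,
             centroids: np.ndarray, uniq: np.ndarray) -> float:
    tot = 0.0
    for ci, lab in enumerate(uniq):
        m = labels == lab
        diff = X[m] - centroids[ci]
        tot += float(np.sum(w[m] * np.sum(diff ** 2, axis=1)))
    return tot


def _centroids(X: np.ndarray, w: np.ndarray, labels: np.ndarray,
               uniq: np.ndarray) -> np.ndarray:
    return np.vstack([
        np.sum(w[labels == lab, None] * X[labels == lab], axis=0) / np.sum(w[labels == lab])
        for lab in uniq])


def cut_and_consolidate(tree: LinkageTree, k: int,
                        scores: pd.DataFrame | np.ndarray, weights=None,
                        max_iter: int = 10,
                        suggestion: KSuggestion | None = None) -> ClusterSolution:
    """Cut the tree at ``k`` clusters and consolidate with weighted k-means.

    The k-means runs at most ``max_iter`` Lloyd iterations from the
    hierarchical centroids (a consolidation, not a re-clustering); its
    objective is monotone, so consolidated within-inertia never exceeds the
    hierarchical one.  A cluster emptied by reassignment is refilled with
    the point nearest its previous centroid (with a warning).
    """
    if isinstance(scores, pd.DataFrame):
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
    n = len(X)
    if not 2 <= k <= n:
        raise ValidationError(f"k={k} outside [2, {n}]")
    w = as_weights(weights, n).astype(float)

    labels0 = cut_tree(tree, k)
    lab = labels0.to_numpy().copy()
    uniq = np.arange(1, k + 1)
    cent = _centroids(X, w, lab, uniq)
    total = _inertia(X, w, np.ones(n, dtype=int), _centroids(X, w, np.ones(n, int), np.array([1])),
                     np.array([1]))
    within0 = _inertia(X, w, lab, cent, uniq)

    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - cent[None, :, :]) ** 2, axis=2)
        new = uniq[np.argmin(d2, axis=1)]
        for ci, label in enumerate(uniq):      # guard against emptied clusters
            if not np.any(new == label):
                warnings.warn(f"cluster {label} emptied during consolidation; "
                              "re-seeded with its nearest point", RuntimeWarning,
                              stacklevel=2)
                new[int(np.argmin(d2[:, ci]))] = label
        if np.array_equal(new, lab):
            break
        lab = new
        cent = _centroids(X, w, lab, uniq)

    within = _inertia(X, w, lab, cent, uniq)
    labels = pd.Series(lab, index=labels0.index, name="cluster")
    sizes = pd.Series({int(u): float(np.sum(w[lab == u])) for u in uniq})
    dims = scores.columns if isinstance(scores, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    return ClusterSolution(
        tree=tree, k=k, labels_initial=labels0, labels=labels,
        total_inertia=total, within_inertia=within, within_inertia_initial=within0,
        cluster_sizes=sizes, cluster_shares=sizes / sizes.sum(),
        n_reassigned=int(np.sum(lab != labels0.to_numpy())),
        suggestion=suggestion,
        centroids=pd.DataFrame(cent, index=uniq, columns=dims),
    )
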