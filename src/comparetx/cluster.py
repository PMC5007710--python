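"""Complete-linkage hierarchical clustering with missing-tolerant distances.

This reimplements the clustering recipe of classic drug-screen analyses
(WinSTAT-style): variables are z-standardized to mean 0 / variance 1,
objects are compared by Euclidean distance over the coordinates both
have measured — rescaled by ``sqrt(m / m_shared)`` so a pair sharing few
coordinates is not spuriously close — and clusters are merged
agglomeratively with the complete-linkage rule (inter-cluster distance =
maximum pairwise member distance), which guarantees non-decreasing merge
heights.

The agglomeration is written in-package rather than delegated because of
two bespoke rules: the missing-value distance above, and a deterministic
tie-break (among equal-distance candidate merges, the pair whose
clusters contain the smallest original leaf indices merges first).  With
no missing data and no ties it coincides with textbook complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "standardize",
    "pairwise_distances",
    "complete_linkage",
    "linkage_from_distances",
    "cut",
]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (variable) to mean 0, variance 1.

    Uses the sample (n-1) standard deviation over non-missing entries;
    missing entries stay missing.  A constant column is an error naming
    the offending variable — it carries no distance information and
    would divide by zero.
    """
    out = {}
    for col in matrix.columns:
        vals = matrix[col].astype(float)
        n = int(vals.notna().sum())
        if n < 2:
            raise DataError(f"variable {col!r} has fewer than 2 observed values")
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DataError(f"variable {col!r} is constant; cannot standardize")
        out[col] = (vals - vals.mean()) / sd
    return pd.DataFrame(out, index=matrix.index)


def _pair_distance(u: np.ndarray, v: np.ndarray, m: int) -> float:
    shared = ~(np.isnan(u) | np.isnan(v))
    m_shared = int(shared.sum())
    if m_shared == 0:
        return np.nan
    diff = u[shared] - v[shared]
    return float(np.sqrt((m / m_shared) * (diff @ diff)))


def pairwise_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """All object-object distances (rows of ``matrix`` are the objects).

    Euclidean over shared non-missing coordinates, rescaled by
    ``sqrt(m / m_shared)`` with ``m`` the total number of variables; with
    no missingness this is plain Euclidean distance.  A pair with zero
    shared coordinates gets a missing distance and a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    n, m = arr.shape
    dist = np.zeros((n, n))
    if not np.isnan(arr).any():
        # fast path: with no missingness the rescaling is 1, plain Euclidean
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(arr))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                d = _pair_distance(arr[i], arr[j], m)
                dist[i, j] = dist[j, i] = d
        if np.isnan(dist).any():
            warnings.warn(
                "object pair(s) share no observed coordinates; distance missing",
                stacklevel=2,
            )
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` holds ``n - 1`` rows ``(node_a, node_b, height)``; leaves
    are nodes ``0 .. n-1`` in ``leaf_ids`` order, the i-th merge creates
    node ``n + i``.  Complete linkage makes heights non-decreasing.
    """

    leaf_ids: tuple
    merges: tuple  # of (node_a, node_b, height)
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height"])

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        children = {}
        for i, (a, b, h) in enumerate(self.merges):
            node = n + i
            children[node] = (a, b)
            height[node] = h

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.leaf_ids[node]}:{bl:g}"
            a, b = children[node]
            h = height[node]
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat k-cluster partition cut from a dendrogram.

    ``labels`` maps leaf id -> cluster number in 1..k, numbered by order
    of first leaf appearance.
    """

    k: int
    labels: pd.Series
    cut_height: float

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def linkage_from_distances(dist: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Agglomerate a precomputed symmetric distance matrix.

    Complete linkage via the exact max-update: after merging clusters A
    and B, ``d(A+B, C) = max(d(A, C), d(B, C))``, which equals the
    maximum over original leaf pairs, so heights are exact maxima of
    input distances (no accumulated arithmetic).  Ties are broken by the
    smallest (min-leaf, min-leaf) index pair of the candidate clusters.
    """
    if method != "complete":
        raise ValueError("only complete linkage is implemented")
    leaf_ids = tuple(dist.index)
    n = len(leaf_ids)
    if n < 2:
        raise DataError("need at least 2 objects to cluster")
    D = dist.to_numpy(dtype=float).copy()
    if np.isnan(D).any():
        raise DataError(
            "missing pairwise distance(s); impute or drop the affected rows"
        )
    np.fill_diagonal(D, np.inf)
    node_id = list(range(n))
    rep = list(range(n))  # smallest original leaf index in each cluster
    merges = []
    for step in range(n - 1):
        h = D.min()
        cand = np.argwhere(D == h)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            key = (min(rep[i], rep[j]), max(rep[i], rep[j]))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        a, b = node_id[i], node_id[j]
        if rep[j] < rep[i]:
            a, b = b, a
        merges.append((a, b, float(h)))
        new_row = np.maximum(D[i], D[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        node_id[i] = n + step
        rep[i] = min(rep[i], rep[j])
        del node_id[j], rep[j]
    return Dendrogram(leaf_ids, tuple(merges))


def complete_linkage(matrix: pd.DataFrame) -> Dendrogram:
    """Cluster the rows of ``matrix`` (objects x variables).

    Computes the missing-tolerant pairwise distances and agglomerates
    them with complete linkage.  Any object pair with no shared observed
    coordinate makes the tree undefined and raises instead.
    """
    return linkage_from_distances(pairwise_distances(matrix))


def cut(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the tree into ``k`` flat clusters by removing the k-1 highest merges.

    Complete-linkage heights are non-decreasing in merge order, so this
    keeps the first ``n - k`` merges.  Clusters are numbered 1..k by the
    order in which their first leaf appears in ``leaf_ids``.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    keep = n - k
    root_of = list(range(n))  # leaf -> current component root node id
    comp: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, (a, b, _h) in enumerate(dendrogram.merges[:keep]):
        node = n + i
        members = comp.pop(a) + comp.pop(b)
        comp[node] = members
        for leaf in members:
            root_of[leaf] = node
    label_of_root: dict[int, int] = {}
    labels = {}
    for leaf_pos, leaf in enumerate(dendrogram.leaf_ids):
        root = root_of[leaf_pos]
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        labels[leaf] = label_of_root[root]
    cut_height = float(dendrogram.merges[keep][2]) if k > 1 else float("inf")
    return ClusterAssignment(
        k, pd.Series(labels, name="cluster").loc[list(dendrogram.leaf_ids)], cut_height
    )
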