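"""Agglomerative complete-linkage clustering with Euclidean distance.

Used to cluster both samples and genes of the standardized biomarker matrix.
The implementation is a plain O(n^3) agglomeration with an explicit,
deterministic tie rule — when two candidate merges are equally distant, the
pair with the smaller (id, id) index pair merges first — so merge histories
are reproducible across platforms.  Trees serialize to Newick with merge
heights as branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ClusterTree", "complete_linkage", "standardize", "standardize_and_cluster"]


@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering.

    ``merges`` lists (left id, right id, height) in merge order; leaves are
    ids 0..n-1 and the i-th merge creates id n+i (scipy convention).  Under
    complete linkage heights are nondecreasing in merge order.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves needs exactly n-1 merges")
        if not self.labels:
            self.labels = [str(i) for i in range(self.n_leaves)]

    def _children(self) -> dict[int, tuple[int, int]]:
        return {self.n_leaves + i: (l, r) for i, (l, r, _) in enumerate(self.merges)}

    def _heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, height) in enumerate(self.merges):
            h[self.n_leaves + i] = height
        return h

    def leaf_order(self) -> list[int]:
        """Leaf indices in display order, tightest (lowest) subtree first."""
        children = self._children()
        heights = self._heights()

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            l, r = children[node]
            # lower subtree drawn first; ties by smaller node id
            first, second = sorted((l, r), key=lambda k: (heights[k], k))
            return walk(first) + walk(second)

        return walk(self.n_leaves + len(self.merges) - 1)

    def cut(self, k: int) -> np.ndarray:
        """Cluster assignment (0..k-1, in leaf order of first appearance) at k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}]")
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, (l, r, _) in enumerate(self.merges[: self.n_leaves - k]):
            new = self.n_leaves + i
            parent[find(l)] = new
            parent[find(r)] = new
        roots: dict[int, int] = {}
        out = np.empty(self.n_leaves, dtype=int)
        for leaf in range(self.n_leaves):
            root = find(leaf)
            out[leaf] = roots.setdefault(root, len(roots))
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent height minus child height."""
        children = self._children()
        heights = self._heights()

        def esc(label: str) -> str:
            return label.replace(" ", "_").replace(",", "|").replace("(", "_").replace(")", "_")

        def walk(node: int, parent_height: float) -> str:
            bl = parent_height - heights[node]
            if node < self.n_leaves:
                return f"{esc(self.labels[node])}:{bl:.6g}"
            l, r = children[node]
            first, second = sorted((l, r), key=lambda k: (heights[k], k))
            inner = ",".join(walk(c, heights[node]) for c in (first, second))
            return f"({inner}):{bl:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        l, r = children[root]
        first, second = sorted((l, r), key=lambda k: (heights[k], k))
        inner = ",".join(walk(c, heights[root]) for c in (first, second))
        return f"({inner});"


def complete_linkage(X: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """Complete-linkage agglomeration of the rows of ``X`` (Euclidean distance).

    Inter-cluster distance is the maximum pairwise member distance.  Ties are
    broken by the smaller (id, id) pair, so the result is deterministic given
    the input row order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    # pairwise Euclidean distances between active clusters, indexed by node id
    diff = X[:, None, :] - X[None, :, :]
    dist = {(i, j): float(np.sqrt((diff[i, j] ** 2).sum())) for i in range(n) for j in range(i)}

    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    cluster_dist = {(min(i, j), max(i, j)): dist[(max(i, j), min(i, j))]
                    for i in range(n) for j in range(i)}
    for _ in range(n - 1):
        # smallest distance; ties to the smaller index pair
        (i, j), h = min(
            ((pair, cluster_dist[pair]) for pair in cluster_dist
             if pair[0] in active and pair[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        merges.append((i, j, h))
        active.remove(i)
        active.remove(j)
        for k in active:
            dik = cluster_dist[(min(i, k), max(i, k))]
            djk = cluster_dist[(min(j, k), max(j, k))]
            cluster_dist[(k, next_id)] = max(dik, djk)
        active.append(next_id)
        next_id += 1
    return ClusterTree(n_leaves=n, merges=merges, labels=list(labels) if labels else [])


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (mean 0, SD 1); zero-variance genes dropped."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = values.index[~keep].tolist()
        logger.warning("dropping %d zero-variance gene(s) before standardization: %s",
                       len(dropped), dropped[:10])
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=values.index[keep], columns=values.columns)


def standardize_and_cluster(values: pd.DataFrame) -> tuple[ClusterTree, ClusterTree]:
    """Standardize a genes x samples matrix and cluster both axes.

    Returns (sample tree, gene tree), both complete-linkage / Euclidean on
    the per-gene z-scored values.
    """
    z = standardize(values)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples after standardization")
    sample_tree = complete_linkage(z.to_numpy().T, labels=list(z.columns))
    gene_tree = complete_linkage(z.to_numpy(), labels=list(z.index))
    return sample_tree, gene_tree
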