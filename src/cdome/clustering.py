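"""Agglomerative hierarchical clustering of cells by expression profile.

Cells are rows of a binary marker grid; distances are Euclidean (the
conventional default of R's ``hclust`` pipelines) or Jaccard (the
principled choice for presence/absence profiles).  The merge sequence uses
Lance–Williams updates for complete, average (UPGMA) and single linkage,
with a fully deterministic tie-break — among all minimum-distance pairs,
the one with the smallest (node id, node id) pair merges first — so runs
are reproducible across platforms.

The dendrogram uses the usual numbering: leaves ``0..n-1``, the j-th merge
creates node ``n + j``.  ``cut_k`` undoes the last ``k - 1`` merges;
``write_newick`` exports an ultrametric tree whose leaf depths equal half
the root height.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import comb
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "pairwise_distance",
    "agglomerate",
    "cut_k",
    "write_newick",
    "newick_string",
    "adjusted_rand_index",
]


def pairwise_distance(grid: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric distance matrix between the rows of a binary grid.

    The Jaccard distance of two all-zero rows is defined as 0 (identical
    profiles), not NaN.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2:
        raise ValueError("grid must be 2-D with at least 2 rows")
    if metric == "euclidean":
        d = squareform(pdist(grid, metric="euclidean"))
    elif metric == "jaccard":
        x = grid > 0
        inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
        union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"metric must be 'euclidean' or 'jaccard', got {metric!r}")
    return d


@dataclass
class Dendrogram:
    """Leaf labels plus n−1 merge events (left id, right id, height)."""

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        used: set[int] = set()
        for j, (a, b, h) in enumerate(self.merges):
            for node in (a, b):
                if not 0 <= node < n + j:
                    raise ValueError(f"merge {j} references node {node} before it exists")
                if node in used:
                    raise ValueError(f"node {node} used as a child twice")
                used.add(node)
            if h < 0:
                raise ValueError(f"merge height must be >= 0, got {h}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def agglomerate(
    distance: np.ndarray, linkage: str = "complete", leaves: Sequence[str] | None = None
) -> Dendrogram:
    """Standard agglomerative merge sequence over a distance matrix.

    Supported linkages: ``complete``, ``average`` (unweighted / UPGMA) and
    ``single``; cluster-to-cluster distances are maintained with the
    Lance–Williams recurrences.  Ties break deterministically by smallest
    (id, id) pair.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be a square matrix")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"linkage must be complete|average|single, got {linkage!r}")
    if leaves is None:
        leaves = [str(i) for i in range(n)]
    leaves = list(leaves)
    if len(leaves) != n:
        raise ValueError("number of leaf labels must match the matrix size")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n

    for _ in range(n - 1):
        a, b = min(dist, key=lambda ij: (dist[ij], ij))
        h = dist[(a, b)]
        merges.append((a, b, h))
        active -= {a, b}
        for c in active:
            dac = dist.pop((min(a, c), max(a, c)))
            dbc = dist.pop((min(b, c), max(b, c)))
            if linkage == "complete":
                d_new = max(dac, dbc)
            elif linkage == "single":
                d_new = min(dac, dbc)
            else:  # average (UPGMA)
                d_new = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            dist[(c, next_id)] = d_new
        del dist[(a, b)]
        size[next_id] = size[a] + size[b]
        active.add(next_id)
        next_id += 1
    return Dendrogram(leaves=leaves, merges=merges)


def cut_k(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels from undoing the last ``k - 1`` merges.

    Labels are numbered by order of first leaf appearance: leaf 0's cluster
    is 0, the next previously unseen cluster is 1, and so on.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j, (a, b, _h) in enumerate(dendrogram.merges[: n - k]):
        parent[find(a)] = parent[find(b)] = n + j

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
        labels[leaf] = seen[root]
    return labels


# -- Newick export -----------------------------------------------------------

_SAFE_LABEL = re.compile(r"[A-Za-z0-9_.\-]+\Z")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def newick_string(dendrogram: Dendrogram) -> str:
    """Ultrametric Newick string with branch lengths from merge heights.

    A node merged at height ``h`` sits at depth ``h / 2`` above the leaves,
    so two leaves merged at ``h`` become ``(A:h/2,B:h/2);``.
    """
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for j, (a, b, h) in enumerate(dendrogram.merges):
        node = n + j
        height[node] = h
        children[node] = (a, b)

    def render(node: int, parent_height: float) -> str:
        length = max(0.0, parent_height / 2 - height[node] / 2)
        if node < n:
            return f"{_quote(dendrogram.leaves[node])}:{length:.10g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{length:.10g}"

    if n == 1:
        return f"{_quote(dendrogram.leaves[0])}:0;"
    root = n + len(dendrogram.merges) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick_string(dendrogram) + "\n")


# -- cluster agreement -------------------------------------------------------


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Computed from the contingency table via the permutation-model expectation:
    ARI = (index − expected) / (max − expected); 1 for identical partitions,
    ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if math.isclose(max_index, expected):
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
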