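"""Marker-commonality network: cells linked by shared POSITIVE markers.

Nodes are cells; an undirected edge joins two cells when at least
``min_shared`` CD molecules are POSITIVE on both, weighted by that count
(the weight matrix is the off-diagonal of ``G @ G.T`` for binary grid
``G``).  Edges also carry the shared marker list, and nodes an optional
cluster attribute for coloring.  Graphs are exchanged as Graph Modelling
Language (GML) files, the plain-text dialect Cytoscape imports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from cdome.expression import ExpressionMatrix, to_binary

__all__ = [
    "build_commonality_graph",
    "commonality_from_grid",
    "write_gml",
    "read_gml",
    "GMLParseError",
]


class GMLParseError(ValueError):
    """Raised when a GML document cannot be parsed."""


def commonality_from_grid(
    grid: np.ndarray,
    cells: Sequence[str],
    markers: Sequence[str],
    min_shared: int = 1,
    cluster_labels: Mapping[str, int] | Sequence[int] | None = None,
) -> nx.Graph:
    """Build the commonality graph from a 0/1 grid (rows = cells)."""
    grid = np.asarray(grid)
    if grid.shape != (len(cells), len(markers)):
        raise ValueError("grid shape must match cell and marker label counts")
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    if cluster_labels is not None and not isinstance(cluster_labels, Mapping):
        cluster_labels = dict(zip(cells, cluster_labels))

    graph = nx.Graph()
    for cell in cells:
        attrs = {}
        if cluster_labels is not None:
            attrs["cluster"] = int(cluster_labels[cell])
        graph.add_node(cell, **attrs)

    shared_counts = grid.astype(np.int64) @ grid.astype(np.int64).T
    marker_arr = np.asarray(markers, dtype=object)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            w = int(shared_counts[i, j])
            if w >= min_shared:
                shared = marker_arr[(grid[i] > 0) & (grid[j] > 0)]
                graph.add_edge(
                    cells[i], cells[j], weight=w, shared=" ".join(str(m) for m in shared)
                )
    return graph


def build_commonality_graph(
    matrix: ExpressionMatrix,
    min_shared: int = 1,
    cluster_labels: Mapping[str, int] | Sequence[int] | None = None,
    unknown_policy: str = "as_negative",
) -> nx.Graph:
    """Commonality graph of a ternary matrix under an UNKNOWN policy."""
    grid, cells, markers = to_binary(matrix, unknown_policy)
    return commonality_from_grid(grid, cells, markers, min_shared, cluster_labels)


def write_gml(graph: nx.Graph, path: str | Path) -> None:
    """Write the graph as a Cytoscape-readable GML document.

    Layout: ``graph [ node [ id label ... ] edge [ source target weight ] ]``;
    labels containing spaces are quoted by the writer.
    """
    nx.write_gml(graph, str(path), stringizer=str)


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML document back; node labels become node names.

    A malformed document raises :class:`GMLParseError` carrying the parser's
    position information.
    """
    try:
        return nx.read_gml(str(path), label="label")
    except nx.NetworkXError as exc:
        raise GMLParseError(f"{path}: {exc}") from exc
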