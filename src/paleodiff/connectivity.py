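"""Least-cost-path distance matrices and the dispersal-thresholded connection graph.

Connectivity between populations is decided by comparing the least-cost path
(LCP, km-equivalent) between two occupied cells with the distance either
population can cover in one time step. Paths are allowed to run through any
landscape class: non-suitable classes are costly, never impassable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from paleodiff.grid import CostGraph

__all__ = ["CostDistanceMatrix", "ConnectionGraph", "least_cost_matrix", "connection_edges", "components"]


@dataclass
class CostDistanceMatrix:
    """All-pairs least-cost distances (km x cost factor) between listed cells."""

    cell_ids: np.ndarray  # linear cell indices, sorted ascending
    values: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("cost matrix shape does not match cell list")

    def index_of(self, cells: np.ndarray) -> np.ndarray:
        """Positions of ``cells`` within ``cell_ids`` (which must contain them)."""
        pos = np.searchsorted(self.cell_ids, cells)
        if np.any(pos >= len(self.cell_ids)) or np.any(self.cell_ids[pos] != cells):
            raise KeyError("cells not covered by this cost-distance matrix")
        return pos

    def submatrix(self, cells: np.ndarray) -> "CostDistanceMatrix":
        idx = self.index_of(np.asarray(cells, dtype=np.int64))
        return CostDistanceMatrix(cell_ids=np.asarray(cells), values=self.values[np.ix_(idx, idx)])


@dataclass
class ConnectionGraph:
    """Occupied cells linked where per-step dispersal exceeds the LCP."""

    nodes: np.ndarray  # occupied cell ids
    edges: np.ndarray  # (m, 2) array of cell-id pairs, i < j
    component_label: np.ndarray  # per node: lowest member cell id of its component


def least_cost_matrix(graph: CostGraph, cells: np.ndarray | list[int]) -> CostDistanceMatrix:
    """Exact all-pairs shortest-path distances between ``cells`` over the full grid.

    Dijkstra runs over every grid cell, so optimal paths may cross cells that
    are not in ``cells`` (and any landscape class).
    """
    cells = np.asarray(cells, dtype=np.int64)
    if cells.size == 0:
        raise ValueError("empty cell list")
    if cells.min() < 0 or cells.max() >= graph.grid.n_cells:
        raise ValueError("cell index out of range")
    cells = np.unique(cells)
    dist = dijkstra(graph.adjacency, directed=False, indices=cells)
    values = dist[:, cells]
    # symmetrize away float round-off from per-source runs
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return CostDistanceMatrix(cell_ids=cells, values=values)


def connection_edges(
    costD: CostDistanceMatrix,
    dispersal_per_step: np.ndarray,
    rule: str = "max",
) -> ConnectionGraph:
    """Connect cell pairs whose per-step dispersal reach strictly exceeds the LCP.

    ``dispersal_per_step`` is km-per-step, aligned with ``costD.cell_ids``.
    Under the default ``max`` rule an edge exists iff
    ``max(d_i, d_j) > LCP(i, j)``: successful movement in either direction is
    enough for genetic exchange. ``min`` requires both populations to reach.
    """
    d = np.asarray(dispersal_per_step, dtype=float)
    if d.shape != costD.cell_ids.shape:
        raise ValueError("dispersal vector must align with costD.cell_ids")
    if np.any(d < 0):
        raise ValueError("negative dispersal distance")
    if rule == "max":
        reach = np.maximum(d[:, None], d[None, :])
    elif rule == "min":
        reach = np.minimum(d[:, None], d[None, :])
    else:
        raise ValueError("rule must be 'max' or 'min'")
    adj = reach > costD.values  # strict: equal LCP does not connect
    np.fill_diagonal(adj, False)

    n = len(costD.cell_ids)
    n_comp, comp = connected_components(adj, directed=False)
    # deterministic naming: component label = lowest member cell id
    label_of_comp = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(label_of_comp, comp, costD.cell_ids)
    labels = label_of_comp[comp]

    iu, ju = np.where(np.triu(adj, k=1))
    edges = np.column_stack([costD.cell_ids[iu], costD.cell_ids[ju]])
    return ConnectionGraph(nodes=costD.cell_ids.copy(), edges=edges, component_label=labels)


def components(graph: ConnectionGraph) -> dict[int, int]:
    """Map cell id -> component label (lowest member cell id)."""
    return {int(c): int(l) for c, l in zip(graph.nodes, graph.component_label)}
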