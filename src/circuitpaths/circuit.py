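"""Raster circuit theory: resistance graphs, pairwise solves, current maps.

The landscape raster is treated as an electrical network: every valid cell
is a vertex, every pair of neighbouring cells is a resistor. Injecting one
ampere at a source cell and grounding a second cell yields (i) the
effective resistance between the pair — the scalar "pairwise resistance"
of isolation-by-resistance analyses — and (ii) a per-cell current
magnitude map whose high-current cells mark the dense bundle of gene-flow
pathways between the pair.

Conventions (fixed so that maps are comparable across runs):

* inter-cell resistance = arithmetic mean of the two cell resistances,
  multiplied by sqrt(2) for diagonal (Queen's case) neighbours;
* per-cell current = half the sum of absolute branch currents incident to
  the cell; the two terminal cells carry the full injected current (1);
* pairs in different graph components get infinite resistance and an
  all-zero current map, with a warning — not an exception.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .grids import GridGeoreference, ResistanceRaster

__all__ = [
    "ResistanceGraph",
    "PairSolution",
    "build_resistance_graph",
    "solve_pair",
    "solve_all_pairs",
]

logger = logging.getLogger(__name__)

_SOLVE_RTOL = 1e-8


class EmptyRasterError(ValueError):
    """Raster contains no valid cells."""


class NodePlacementError(ValueError):
    """A network node cannot be snapped onto a valid cell."""


class NumericalFailureError(RuntimeError):
    """Linear solve failed to reach the required residual tolerance."""


# queen-8 neighbour offsets, lower half only (undirected edges counted once)
_ORTHO = ((0, 1), (1, 0))
_DIAG = ((1, 1), (1, -1))


@dataclass
class ResistanceGraph:
    """Sparse conductance graph over the valid cells of a raster."""

    georef: GridGeoreference
    vertex_of_cell: np.ndarray        # (n_rows, n_cols) int, -1 where invalid
    cells: np.ndarray                 # (n_vertices, 2) row/col per vertex
    edge_u: np.ndarray                # (n_edges,) vertex indices
    edge_v: np.ndarray
    conductance: np.ndarray           # (n_edges,) 1/resistance
    component: np.ndarray             # (n_vertices,) component label
    neighborhood: str = "queen-8"
    _solvers: dict = field(default_factory=dict, repr=False)
    _incidence: Optional[sp.csr_matrix] = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.cells.shape[0]

    @property
    def n_components(self) -> int:
        return int(self.component.max()) + 1 if self.n_vertices else 0

    def vertex_at(self, row: int, col: int) -> int:
        v = int(self.vertex_of_cell[row, col])
        if v < 0:
            raise NodePlacementError(f"cell ({row}, {col}) is nodata")
        return v

    def snap_cell(self, row: int, col: int, node_name: str = "?") -> int:
        """Vertex for a cell, falling back to the nearest valid cell within
        one cell radius (lower row, then lower column breaks ties)."""
        if 0 <= row < self.georef.n_rows and 0 <= col < self.georef.n_cols:
            v = int(self.vertex_of_cell[row, col])
            if v >= 0:
                return v
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = row + dr, col + dc
                if 0 <= r < self.georef.n_rows and 0 <= c < self.georef.n_cols:
                    v = int(self.vertex_of_cell[r, c])
                    if v >= 0:
                        return v
        raise NodePlacementError(
            f"node {node_name!r} at cell ({row}, {col}) has no valid cell "
            "within one cell radius"
        )

    # -- Laplacian machinery -------------------------------------------------

    def laplacian(self) -> sp.csr_matrix:
        n = self.n_vertices
        i = np.concatenate([self.edge_u, self.edge_v])
        j = np.concatenate([self.edge_v, self.edge_u])
        g = np.concatenate([self.conductance, self.conductance])
        off = sp.coo_matrix((-g, (i, j)), shape=(n, n))
        deg = np.zeros(n)
        np.add.at(deg, self.edge_u, self.conductance)
        np.add.at(deg, self.edge_v, self.conductance)
        return (off + sp.diags(deg)).tocsr()

    def _component_solver(self, comp: int):
        """Cached LU factorization of the component Laplacian with its first
        vertex grounded (removed); reused across all pairs in the component."""
        if comp not in self._solvers:
            members = np.flatnonzero(self.component == comp)
            local = -np.ones(self.n_vertices, dtype=np.int64)
            local[members] = np.arange(members.size)
            lap = self.laplacian()[members][:, members].tocsc()
            if members.size == 1:
                lu = None
            else:
                lu = splu(lap[1:, 1:].tocsc())
            self._solvers[comp] = (members, local, lap, lu)
        return self._solvers[comp]


def build_resistance_graph(raster: ResistanceRaster,
                           neighborhood: str = "queen-8") -> ResistanceGraph:
    """Convert a resistance raster into an undirected conductance graph.

    Parameters
    ----------
    raster : ResistanceRaster
    neighborhood : {"queen-8", "rook-4"}
        Queen's case (orthogonal + diagonal moves) is the default, matching
        standard raster circuit analyses; rook-4 restricts to orthogonal
        neighbours.
    """
    if neighborhood not in ("queen-8", "rook-4"):
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    georef = raster.georef
    valid = georef.valid_mask() & np.isfinite(raster.values)
    n = int(np.count_nonzero(valid))
    if n == 0:
        raise EmptyRasterError("raster has no valid cells")

    vertex_of_cell = -np.ones(georef.shape, dtype=np.int64)
    rows, cols = np.nonzero(valid)
    vertex_of_cell[rows, cols] = np.arange(n)
    cells = np.column_stack([rows, cols])

    res = raster.values
    eu, ev, g = [], [], []
    offsets = _ORTHO + (_DIAG if neighborhood == "queen-8" else ())
    for dr, dc in offsets:
        a = valid[max(0, -dr):georef.n_rows - max(0, dr),
                  max(0, -dc):georef.n_cols - max(0, dc)]
        b = valid[max(0, dr):georef.n_rows + min(0, dr),
                  max(0, dc):georef.n_cols + min(0, dc)]
        both = a & b
        r0, c0 = np.nonzero(both)
        r0 = r0 + max(0, -dr)
        c0 = c0 + max(0, -dc)
        r1, c1 = r0 + dr, c0 + dc
        pair_res = 0.5 * (res[r0, c0] + res[r1, c1])
        if (dr, dc) in _DIAG:
            pair_res = pair_res * np.sqrt(2.0)
        eu.append(vertex_of_cell[r0, c0])
        ev.append(vertex_of_cell[r1, c1])
        g.append(1.0 / pair_res)

    edge_u = np.concatenate(eu) if eu else np.empty(0, dtype=np.int64)
    edge_v = np.concatenate(ev) if ev else np.empty(0, dtype=np.int64)
    conductance = np.concatenate(g) if g else np.empty(0)

    adj = sp.coo_matrix(
        (np.ones(edge_u.size), (edge_u, edge_v)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    return ResistanceGraph(georef, vertex_of_cell, cells, edge_u, edge_v,
                           conductance, labels, neighborhood)


@dataclass
class PairSolution:
    """Circuit solution for one source/ground pair."""

    edge_id: object
    source_node: object
    ground_node: object
    effective_resistance: float
    current_map: np.ndarray
    georef: GridGeoreference

    @property
    def is_finite(self) -> bool:
        return np.isfinite(self.effective_resistance)


def _solve_vertices(graph: ResistanceGraph, vs: int, vt: int,
                    edge_id=None, source_node=None, ground_node=None) -> PairSolution:
    georef = graph.georef
    current = np.zeros(georef.shape)
    if graph.component[vs] != graph.component[vt]:
        logger.warning(
            "pair %r: source and ground lie in different components; "
            "reporting infinite resistance", edge_id,
        )
        return PairSolution(edge_id, source_node, ground_node, np.inf,
                            current, georef)

    comp = int(graph.component[vs])
    members, local, lap, lu = graph._component_solver(comp)
    m = members.size
    ls, lt = int(local[vs]), int(local[vt])

    b = np.zeros(m)
    b[ls] += 1.0
    b[lt] -= 1.0
    v = np.zeros(m)
    if lu is not None:
        v[1:] = lu.solve(b[1:])
    residual = np.linalg.norm(lap @ v - b)
    if residual > _SOLVE_RTOL * np.linalg.norm(b):
        raise NumericalFailureError(
            f"linear solve residual {residual:.3e} exceeds tolerance"
        )
    v -= v[lt]  # ground at zero potential; v[ls] is then R_eff

    # branch currents within the component
    in_comp = graph.component[graph.edge_u] == comp
    u_loc = local[graph.edge_u[in_comp]]
    w_loc = local[graph.edge_v[in_comp]]
    branch = (v[u_loc] - v[w_loc]) * graph.conductance[in_comp]

    node_cur = np.zeros(m)
    np.add.at(node_cur, u_loc, np.abs(branch))
    np.add.at(node_cur, w_loc, np.abs(branch))
    node_cur *= 0.5
    node_cur[ls] = 1.0  # terminals carry the full injected current
    node_cur[lt] = 1.0

    cells = graph.cells[members]
    current[cells[:, 0], cells[:, 1]] = node_cur
    return PairSolution(edge_id, source_node, ground_node, float(v[ls]),
                        current, georef)


def solve_pair(graph: ResistanceGraph, source_cell: tuple[int, int],
               ground_cell: tuple[int, int], edge_id=None) -> PairSolution:
    """Solve one source/ground pair given as (row, col) cells.

    Unit current is injected at the source and the ground cell is held at
    zero potential; the effective resistance is the resulting source
    potential. Disconnected pairs yield infinite resistance with an
    all-zero current map (warning logged), not an exception.
    """
    if tuple(source_cell) == tuple(ground_cell):
        raise ValueError("source and ground cells must differ")
    vs = graph.vertex_at(*source_cell)
    vt = graph.vertex_at(*ground_cell)
    return _solve_vertices(graph, vs, vt, edge_id=edge_id,
                           source_node=tuple(source_cell),
                           ground_node=tuple(ground_cell))


def solve_all_pairs(graph: ResistanceGraph, network) -> Iterator[PairSolution]:
    """Solve every edge of a genetic network, in edge-id order.

    Node coordinates are snapped to the containing cell centre (nearest
    valid cell within one cell radius if that cell is nodata). Yields one
    :class:`PairSolution` per edge; solutions are independent across pairs,
    so any evaluation order gives identical results.
    """
    georef = graph.georef
    vertex_of_node: dict = {}
    for node in network.nodes.itertuples(index=False):
        row, col = georef.cell_of(node.x, node.y)
        vertex_of_node[node.id] = graph.snap_cell(row, col, node_name=str(node.id))

    edges = network.edges.sort_values("id")
    for e in edges.itertuples(index=False):
        vs = vertex_of_node[e.node_a]
        vt = vertex_of_node[e.node_b]
        yield _solve_vertices(graph, vs, vt, edge_id=e.id,
                              source_node=e.node_a, ground_node=e.node_b)


def resistance_table(solutions) -> "pd.DataFrame":
    """Collect PairSolutions into a pairwise-resistance table."""
    import pandas as pd

    rows = [
        (s.edge_id, s.source_node, s.ground_node, s.effective_resistance)
        for s in solutions
    ]
    return pd.DataFrame(rows, columns=["edge_id", "node_a", "node_b",
                                       "effective_resistance"])
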