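"""Synthetic landscapes, genetic networks, polygons and land-cover layers.

The deposited range-wide inputs of the reference analysis (composite
resistance surface, empirical genetic network, PAC/MZ polygons, land-cover
imagery) are cluster-scale downloads; this module generates desk-scale
stand-ins with the statistical structure the analysis assumes:

* spatially autocorrelated resistance fields (smoothed white noise,
  affinely rescaled into the stated 1..161 range at 1200 m cells) with
  optional planted low-resistance corridors;
* nodes placed preferentially in permeable cells (weight = 1/resistance),
  mimicking breeding sites sitting in low-resistance habitat;
* genetic edge weights decaying with pairwise *effective resistance*
  (not Euclidean distance), so network and landscape structure agree and
  parameter-recovery tests are meaningful;
* PAC-like polygon blobs around node clusters and a management-zone
  partition; clustered binary cultivation and fractional canopy layers.

Every generator is a pure function of its spec + a single integer seed.
``fixture_suite`` additionally returns micro-landscapes whose effective
resistances are known analytically or from a dense-pseudoinverse oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, box
from shapely.ops import unary_union

from . import circuit
from .grids import GridGeoreference, LandCoverRaster, ResistanceRaster
from .network import GeneticNetwork

__all__ = [
    "LandscapeSpec", "NetworkSpec", "Fixture", "SyntheticScene",
    "generate_resistance_raster", "generate_nodes", "generate_network",
    "generate_polygons", "generate_landcover", "fixture_suite",
    "generate_scene", "corridor_scene",
]

MZ_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")


class GenerationError(RuntimeError):
    """Generator could not satisfy its postconditions."""


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a synthetic resistance raster.

    Defaults follow the reference landscape's conventions: 1200 m cells
    and resistance spanning 1 (most permeable) to 161 (least permeable).
    """

    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 1200.0
    resistance_range: tuple[float, float] = (1.0, 161.0)
    autocorrelation_scale: float = 5.0  # Gaussian kernel sigma, in cells
    n_corridors: int = 0
    corridor_resistance: float = 1.0
    seed: int = 0
    crs_label: str = "synthetic-albers"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("landscape must be at least 2x2")
        low, high = self.resistance_range
        if not (0 < low <= high):
            raise ValueError("resistance_range must be positive with low <= high")
        if self.n_corridors < 0:
            raise ValueError("n_corridors must be non-negative")
        if self.n_corridors and not 0 < self.corridor_resistance <= low:
            raise ValueError(
                "corridor_resistance must be positive and <= background low")


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a synthetic genetic network over placed nodes."""

    n_nodes: int = 15
    edge_rule: str = "complete"  # {"complete", "all-pairs-within-radius", "gabriel"}
    weight_decay: float = 0.3    # covariance = exp(-decay * effective resistance)
    noise_sd: float = 0.0
    radius_m: Optional[float] = None  # for all-pairs-within-radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.weight_decay < 0 or self.noise_sd < 0:
            raise ValueError("weight_decay and noise_sd must be non-negative")
        if self.edge_rule not in ("complete", "all-pairs-within-radius", "gabriel"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")
        if self.edge_rule == "all-pairs-within-radius" and not self.radius_m:
            raise ValueError("radius_m required for all-pairs-within-radius")


def _line_cells(r0, c0, r1, c1) -> list[tuple[int, int]]:
    """Cells along the segment between two cell centres (dense sampling;
    the result is an 8-connected band)."""
    n = 2 * max(abs(r1 - r0), abs(c1 - c0)) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    seen, cells = set(), []
    for r, c in zip(rr, cc):
        if (r, c) not in seen:
            seen.add((r, c))
            cells.append((r, c))
    return cells


def generate_resistance_raster(spec: LandscapeSpec) -> ResistanceRaster:
    """Autocorrelated resistance field with optional planted corridors.

    White noise is convolved with a Gaussian kernel (sigma =
    ``autocorrelation_scale`` cells) and affinely rescaled into
    ``resistance_range``; each requested corridor is a straight band of
    ``corridor_resistance`` between two random well-separated cells. The
    planted-corridor mask is attached as ``raster.corridor_mask``.
    """
    rng = np.random.default_rng(spec.seed)
    low, high = spec.resistance_range
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    if spec.autocorrelation_scale > 0:
        field_ = ndimage.gaussian_filter(noise, spec.autocorrelation_scale,
                                         mode="reflect")
    else:
        field_ = noise
    lo, hi = field_.min(), field_.max()
    if hi > lo:
        values = low + (field_ - lo) * (high - low) / (hi - lo)
    else:
        values = np.full(field_.shape, low)

    corridor_mask = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    min_sep = max(spec.n_rows, spec.n_cols) // 2
    for _ in range(spec.n_corridors):
        for _attempt in range(100):
            r0, c0 = int(rng.integers(spec.n_rows)), int(rng.integers(spec.n_cols))
            r1, c1 = int(rng.integers(spec.n_rows)), int(rng.integers(spec.n_cols))
            if max(abs(r1 - r0), abs(c1 - c0)) >= min_sep:
                break
        for r, c in _line_cells(r0, c0, r1, c1):
            corridor_mask[r, c] = True
    values[corridor_mask] = spec.corridor_resistance

    georef = GridGeoreference(spec.n_rows, spec.n_cols, spec.cell_size,
                              crs_label=spec.crs_label)
    return ResistanceRaster(georef, values,
                            corridor_mask=corridor_mask if spec.n_corridors else None)


def generate_nodes(raster: ResistanceRaster, n: int, seed: int = 0) -> pd.DataFrame:
    """Place ``n`` distinct nodes at cell centres, preferring permeable cells.

    Sampling weight of a candidate cell is proportional to 1/resistance
    (breeding sites sit in permeable habitat), without replacement.
    """
    if n < 1:
        raise ValueError("n must be positive")
    georef = raster.georef
    valid = georef.valid_mask() & np.isfinite(raster.values)
    rows, cols = np.nonzero(valid)
    if rows.size < n:
        raise GenerationError(
            f"requested {n} nodes but only {rows.size} valid cells")
    w = 1.0 / raster.values[rows, cols]
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False, p=w / w.sum())
    xy = [georef.cell_center(rows[i], cols[i]) for i in pick]
    return pd.DataFrame({"id": np.arange(n),
                         "x": [p[0] for p in xy], "y": [p[1] for p in xy]})


def _gabriel_pairs(xy: np.ndarray) -> list[tuple[int, int]]:
    """Gabriel graph edges: (a, b) kept iff no third point falls inside the
    circle with segment ab as diameter. O(n^3); fine at synthetic sizes."""
    n = len(xy)
    pairs = []
    for a in range(n):
        for b in range(a + 1, n):
            mid = (xy[a] + xy[b]) / 2
            r2 = ((xy[a] - xy[b]) ** 2).sum() / 4
            d2 = ((xy - mid) ** 2).sum(axis=1)
            d2[a] = d2[b] = np.inf
            if np.all(d2 > r2 + 1e-9):
                pairs.append((a, b))
    return pairs


def generate_network(nodes: pd.DataFrame, raster: ResistanceRaster,
                     spec: NetworkSpec) -> GeneticNetwork:
    """Genetic network with resistance-decaying covariance weights.

    weight = exp(-weight_decay x effective_resistance) + N(0, noise_sd),
    floored at 1e-6. Effective resistances come from the circuit solver on
    the supplied raster, so the network "sees" the same landscape the
    downstream analysis does. If the chosen edge rule leaves the network
    disconnected, minimum-resistance bridging edges are added across
    components.
    """
    rng = np.random.default_rng(spec.seed)
    graph = circuit.build_resistance_graph(raster)
    georef = raster.georef
    n = len(nodes)
    verts = []
    for node in nodes.itertuples(index=False):
        r, c = georef.cell_of(node.x, node.y)
        verts.append(graph.snap_cell(r, c, node_name=str(node.id)))

    xy = nodes[["x", "y"]].to_numpy(dtype=float)
    if spec.edge_rule == "complete":
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    elif spec.edge_rule == "all-pairs-within-radius":
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
                 if np.hypot(*(xy[a] - xy[b])) <= spec.radius_m]
    else:
        pairs = _gabriel_pairs(xy)

    def reff(a: int, b: int) -> float:
        if verts[a] == verts[b]:
            return 0.0
        return circuit._solve_vertices(graph, verts[a], verts[b]).effective_resistance

    # bridge components until connected (at most n-1 additions)
    ids = nodes["id"].to_numpy()
    adj = {i: set() for i in range(n)}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)

    def components() -> list[set[int]]:
        seen, comps = set(), []
        for s in range(n):
            if s in seen:
                continue
            stack, comp = [s], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    comps = components()
    guard = 0
    while len(comps) > 1:
        guard += 1
        if guard > n:
            raise GenerationError("could not connect the synthetic network")
        main, rest = comps[0], set().union(*comps[1:])
        best = min(((a, b) for a in sorted(main) for b in sorted(rest)),
                   key=lambda ab: ((xy[ab[0]] - xy[ab[1]]) ** 2).sum())
        pairs.append(tuple(sorted(best)))
        adj[best[0]].add(best[1])
        adj[best[1]].add(best[0])
        comps = components()

    pairs = sorted(set(pairs))
    rows = []
    for eid, (a, b) in enumerate(pairs):
        w = float(np.exp(-spec.weight_decay * reff(a, b)))
        if spec.noise_sd > 0:
            w += float(rng.normal(0.0, spec.noise_sd))
        rows.append((eid, ids[a], ids[b], max(w, 1e-6)))
    edges = pd.DataFrame(rows, columns=["id", "node_a", "node_b", "weight"])
    net = GeneticNetwork(nodes.copy(), edges)
    if not net.is_connected():
        raise GenerationError("synthetic network is disconnected after bridging")
    return net


def generate_polygons(nodes: pd.DataFrame, georef: GridGeoreference,
                      kind: str, coverage: float = 0.30, k: int = 3,
                      seed: int = 0):
    """Synthetic conservation polygons.

    kind="pac": blobs buffered around node positions, with the buffer
    radius bisected so the rasterized footprint covers ~``coverage`` of
    the grid (default 0.30 — the reference PACs cover roughly a quarter
    to a third of the range). Returns (polygons, labels).
    kind="mz": a partition of the grid extent into ``k`` equal-width
    vertical bands labelled with roman numerals.
    """
    from .overlay import rasterize_polygons  # local import avoids a cycle

    if kind == "mz":
        if not 1 <= k <= len(MZ_LABELS):
            raise ValueError(f"k must be in 1..{len(MZ_LABELS)}")
        xmin, ymin, xmax, ymax = georef.bounds
        width = (xmax - xmin) / k
        polys = [box(xmin + i * width, ymin, xmin + (i + 1) * width, ymax)
                 for i in range(k)]
        return polys, list(MZ_LABELS[:k])
    if kind != "pac":
        raise ValueError(f"unknown polygon kind {kind!r}")
    if not 0 < coverage < 1:
        raise ValueError("coverage fraction must lie in (0, 1)")

    pts = [Point(x, y) for x, y in nodes[["x", "y"]].to_numpy()]
    n_cells = int(np.count_nonzero(georef.valid_mask()))

    def covered(radius: float) -> float:
        geom = unary_union([p.buffer(radius, quad_segs=8) for p in pts])
        zone = rasterize_polygons([geom], georef, label="pac-trial")
        return np.count_nonzero(zone.mask) / n_cells

    lo, hi = georef.cell_size * 0.5, georef.cell_size * max(georef.n_rows,
                                                            georef.n_cols)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if covered(mid) < coverage:
            lo = mid
        else:
            hi = mid
    radius = 0.5 * (lo + hi)
    blob = unary_union([p.buffer(radius, quad_segs=8) for p in pts])
    polys = list(blob.geoms) if blob.geom_type == "MultiPolygon" else [blob]
    return polys, [f"pac-{i}" for i in range(len(polys))]


def generate_landcover(georef: GridGeoreference, kind: str,
                       patch_density: float = 0.1, seed: int = 0,
                       patch_scale: float = 2.0) -> LandCoverRaster:
    """Patchy land-cover layer.

    kind="cultivation": binary clustered patches covering ~``patch_density``
    of the grid. kind="canopy": continuous cover in [0, 1], nonzero on
    ~``patch_density`` of cells. ``patch_scale`` is the smoothing sigma in
    cells (patch size).
    """
    if kind not in ("cultivation", "canopy"):
        raise ValueError(f"unknown landcover kind {kind!r}")
    if not 0 <= patch_density <= 1:
        raise ValueError("patch_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if patch_density == 0:
        vals = np.zeros(georef.shape)
        return LandCoverRaster(georef, vals, kind=kind)
    field_ = ndimage.gaussian_filter(rng.standard_normal(georef.shape),
                                     patch_scale, mode="reflect")
    thr = np.quantile(field_, 1.0 - patch_density)
    patch = field_ >= thr
    if kind == "cultivation":
        vals = patch.astype(float)
    else:
        vals = np.zeros(georef.shape)
        span = field_.max() - thr
        if span > 0:
            vals[patch] = np.clip((field_[patch] - thr) / span, 0.0, 1.0)
        else:
            vals[patch] = 1.0
    return LandCoverRaster(georef, vals, kind=kind)


# ---------------------------------------------------------------------------
# deterministic micro-fixtures with known circuit answers


@dataclass
class Fixture:
    name: str
    raster: ResistanceRaster
    terminals: tuple[tuple[int, int], tuple[int, int]]
    expected_resistance: float  # np.inf for disconnected pairs
    neighborhood: str = "queen-8"
    nodes: Optional[pd.DataFrame] = None
    corridor_mask: Optional[np.ndarray] = None


def _dense_effective_resistance(n_vertices: int,
                                edges: Sequence[tuple[int, int, float]],
                                s: int, t: int) -> float:
    """Laplacian-pseudoinverse oracle on an explicit tiny edge list.

    Independent of the sparse solver: builds the dense Laplacian and uses
    numpy's pinv; R_eff = (e_s - e_t)^T L+ (e_s - e_t).
    """
    lap = np.zeros((n_vertices, n_vertices))
    for a, b, resistance in edges:
        g = 1.0 / resistance
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g
    pinv = np.linalg.pinv(lap)
    e = np.zeros(n_vertices)
    e[s], e[t] = 1.0, -1.0
    return float(e @ pinv @ e)


def fixture_suite(cell_size: float = 1200.0) -> dict[str, Fixture]:
    """Named micro-landscapes bundled with expected effective resistances.

    * chain-1x3 — resistances (2, 4, 6): inter-cell resistances are the
      adjacent-cell means 3 and 5, so the endpoint pair sees 8 (series law).
    * uniform-2x2 — unit resistance, Queen's case: corner-to-adjacent-corner
      value from the dense pseudoinverse oracle on the 4-vertex graph.
    * two-component — a nodata band splits the grid; resistance is infinite.
    * corridor-50x50 — a 21-cell resistance-1 corridor through a rough
      high-resistance background, two nodes at the corridor endpoints; no
      closed form (expected resistance NaN), used for corridor-recovery.
    """
    fixtures: dict[str, Fixture] = {}

    g13 = GridGeoreference(1, 3, cell_size, crs_label="synthetic-albers")
    fixtures["chain-1x3"] = Fixture(
        "chain-1x3", ResistanceRaster(g13, np.array([[2.0, 4.0, 6.0]])),
        ((0, 0), (0, 2)), expected_resistance=8.0)

    g22 = GridGeoreference(2, 2, cell_size, crs_label="synthetic-albers")
    # Queen's case on 4 unit cells: 4 orthogonal resistors of 1, 2 diagonal
    # of sqrt(2); vertices row-major 0..3, terminals corner (0,0)->(0,1)
    rt2 = float(np.sqrt(2.0))
    edges22 = [(0, 1, 1.0), (2, 3, 1.0), (0, 2, 1.0), (1, 3, 1.0),
               (0, 3, rt2), (1, 2, rt2)]
    fixtures["uniform-2x2"] = Fixture(
        "uniform-2x2", ResistanceRaster(g22, np.ones((2, 2))),
        ((0, 0), (0, 1)),
        expected_resistance=_dense_effective_resistance(4, edges22, 0, 1))

    band = np.zeros((3, 3), dtype=bool)
    band[1, :] = True
    g33 = GridGeoreference(3, 3, cell_size, crs_label="synthetic-albers",
                           nodata_mask=band)
    fixtures["two-component"] = Fixture(
        "two-component", ResistanceRaster(g33, np.ones((3, 3))),
        ((0, 1), (2, 1)), expected_resistance=np.inf)

    fixtures["corridor-50x50"] = _corridor_fixture(cell_size)
    return fixtures


_CORRIDOR_ROW = 25
_CORRIDOR_COLS = (15, 35)  # inclusive endpoints -> 21 corridor cells


def _corridor_fixture(cell_size: float = 1200.0, seed: int = 2025) -> Fixture:
    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.standard_normal((50, 50)), 4.0,
                                     mode="reflect")
    lo, hi = field_.min(), field_.max()
    values = 60.0 + (field_ - lo) * (161.0 - 60.0) / (hi - lo)
    c0, c1 = _CORRIDOR_COLS
    corridor = np.zeros((50, 50), dtype=bool)
    corridor[_CORRIDOR_ROW, c0:c1 + 1] = True
    values[corridor] = 1.0
    georef = GridGeoreference(50, 50, cell_size, crs_label="synthetic-albers")
    raster = ResistanceRaster(georef, values, corridor_mask=corridor)
    endpoints = ((_CORRIDOR_ROW, c0), (_CORRIDOR_ROW, c1))
    xy = [georef.cell_center(*cell) for cell in endpoints]
    nodes = pd.DataFrame({"id": [0, 1], "x": [p[0] for p in xy],
                          "y": [p[1] for p in xy]})
    return Fixture("corridor-50x50", raster, endpoints,
                   expected_resistance=float("nan"), nodes=nodes,
                   corridor_mask=corridor)


def corridor_scene(seed: int = 2025, cell_size: float = 1200.0):
    """The corridor-50x50 fixture plus its two-node, one-edge network."""
    fx = _corridor_fixture(cell_size, seed=seed)
    edges = pd.DataFrame({"id": [0], "node_a": [0], "node_b": [1],
                          "weight": [1.0]})
    return fx, GeneticNetwork(fx.nodes.copy(), edges)


@dataclass
class SyntheticScene:
    """A complete synthetic input bundle for the end-to-end pipeline."""

    raster: ResistanceRaster
    nodes: pd.DataFrame
    network: GeneticNetwork
    pac_polygons: list
    pac_labels: list
    mz_polygons: list
    mz_labels: list
    cultivation: LandCoverRaster
    canopy: LandCoverRaster
    seed: int


def generate_scene(seed: int = 0, landscape: Optional[LandscapeSpec] = None,
                   net: Optional[NetworkSpec] = None,
                   pac_coverage: float = 0.30, n_mz: int = 5,
                   cultivation_density: float = 0.15,
                   canopy_density: float = 0.15) -> SyntheticScene:
    """Generate all four input classes from one seed.

    Per-stage seeds are derived from the scene seed so stages stay
    independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    landscape = landscape or LandscapeSpec(n_corridors=2,
                                           corridor_resistance=1.0,
                                           seed=sub[0])
    net = net or NetworkSpec(seed=sub[2])
    raster = generate_resistance_raster(landscape)
    nodes = generate_nodes(raster, net.n_nodes, seed=sub[1])
    network = generate_network(nodes, raster, net)
    pac_polys, pac_labels = generate_polygons(nodes, raster.georef, "pac",
                                              coverage=pac_coverage, seed=sub[3])
    mz_polys, mz_labels = generate_polygons(nodes, raster.georef, "mz",
                                            k=n_mz, seed=sub[3])
    cult = generate_landcover(raster.georef, "cultivation",
                              patch_density=cultivation_density, seed=sub[4])
    canopy = generate_landcover(raster.georef, "canopy",
                                patch_density=canopy_density, seed=sub[5])
    return SyntheticScene(raster, nodes, network, pac_polys, pac_labels,
                          mz_polys, mz_labels, cult, canopy, seed)
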