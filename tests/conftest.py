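"""Shared fixtures: micro-landscapes, the corridor scene, and a dense
Laplacian-pseudoinverse circuit oracle that is independent of the sparse
solver under test (its edge construction and current bookkeeping are
re-derived here in plain Python loops)."""

import numpy as np
import pytest

from circuitpaths import synthetic
from circuitpaths.grids import GridGeoreference, ResistanceRaster


@pytest.fixture(scope="session")
def fixtures():
    return synthetic.fixture_suite()


@pytest.fixture(scope="session")
def corridor():
    """(fixture, two-node network) for the corridor-50x50 scene."""
    return synthetic.corridor_scene()


def make_raster(values, cell_size=1200.0, nodata=None, crs="synthetic-albers"):
    values = np.asarray(values, dtype=float)
    georef = GridGeoreference(values.shape[0], values.shape[1], cell_size,
                              crs_label=crs, nodata_mask=nodata)
    return ResistanceRaster(georef, values)


class DenseCircuitOracle:
    """Brute-force circuit solution on a tiny raster.

    Rebuilds the cell graph with explicit loops (arithmetic-mean inter-cell
    resistance, sqrt(2) factor on diagonals), forms the dense Laplacian and
    uses numpy's pseudoinverse. Shares no code with circuitpaths.circuit.
    """

    def __init__(self, raster, neighborhood="queen-8"):
        self.georef = raster.georef
        valid = raster.georef.valid_mask() & np.isfinite(raster.values)
        self.index = -np.ones(raster.georef.shape, dtype=int)
        cells = list(zip(*np.nonzero(valid)))
        for k, (r, c) in enumerate(cells):
            self.index[r, c] = k
        self.cells = cells
        n = len(cells)
        offsets = [(0, 1), (1, 0)]
        if neighborhood == "queen-8":
            offsets += [(1, 1), (1, -1)]
        self.edges = []
        for r, c in cells:
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if (0 <= rr < raster.georef.n_rows
                        and 0 <= cc < raster.georef.n_cols
                        and self.index[rr, cc] >= 0):
                    res = (raster.values[r, c] + raster.values[rr, cc]) / 2.0
                    if dr and dc:
                        res *= np.sqrt(2.0)
                    self.edges.append((self.index[r, c], self.index[rr, cc],
                                       res))
        lap = np.zeros((n, n))
        for a, b, res in self.edges:
            g = 1.0 / res
            lap[a, a] += g
            lap[b, b] += g
            lap[a, b] -= g
            lap[b, a] -= g
        self.lap = lap
        self.pinv = np.linalg.pinv(lap)
        self.n = n

    def effective_resistance(self, s_cell, t_cell):
        s, t = self.index[s_cell], self.index[t_cell]
        e = np.zeros(self.n)
        e[s], e[t] = 1.0, -1.0
        return float(e @ self.pinv @ e)

    def current_map(self, s_cell, t_cell):
        s, t = self.index[s_cell], self.index[t_cell]
        e = np.zeros(self.n)
        e[s], e[t] = 1.0, -1.0
        v = self.pinv @ e
        node_current = np.zeros(self.n)
        for a, b, res in self.edges:
            i = abs((v[a] - v[b]) / res)
            node_current[a] += i / 2.0
            node_current[b] += i / 2.0
        node_current[s] = 1.0
        node_current[t] = 1.0
        grid = np.zeros(self.georef.shape)
        for k, (r, c) in enumerate(self.cells):
            grid[r, c] = node_current[k]
        return grid


@pytest.fixture
def dense_oracle():
    return DenseCircuitOracle


def random_small_raster(rng, max_cells=25, nodata_prob=0.0):
    """Random raster with at most max_cells cells, resistances in [1, 161]."""
    while True:
        n_rows = int(rng.integers(2, 6))
        n_cols = int(rng.integers(2, 6))
        if n_rows * n_cols <= max_cells:
            break
    values = rng.uniform(1.0, 161.0, size=(n_rows, n_cols))
    nodata = None
    if nodata_prob > 0:
        nodata = rng.random((n_rows, n_cols)) < nodata_prob
        if nodata.all():
            nodata[0, 0] = False
    georef = GridGeoreference(n_rows, n_cols, 1200.0,
                              crs_label="synthetic-albers", nodata_mask=nodata)
    return ResistanceRaster(georef, values)
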