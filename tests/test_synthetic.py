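"""Synthetic generators: determinism, value ranges, corridor structure,
placement weights, network construction, polygons and land cover."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from circuitpaths import circuit, overlay, synthetic
from circuitpaths.grids import GridGeoreference
from circuitpaths.synthetic import LandscapeSpec, NetworkSpec

from conftest import make_raster


class TestResistanceRaster:
    def test_degenerate_range_gives_uniform_ones(self):
        spec = LandscapeSpec(n_rows=10, n_cols=10, resistance_range=(1, 1),
                             n_corridors=0, seed=3)
        raster = synthetic.generate_resistance_raster(spec)
        np.testing.assert_array_equal(raster.values, 1.0)

    def test_identical_spec_identical_raster(self):
        spec = LandscapeSpec(n_rows=100, n_cols=100,
                             autocorrelation_scale=8, seed=7)
        a = synthetic.generate_resistance_raster(spec)
        b = synthetic.generate_resistance_raster(spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_values_respect_range_and_floor(self):
        spec = LandscapeSpec(n_rows=40, n_cols=40,
                             resistance_range=(1, 161), seed=1)
        raster = synthetic.generate_resistance_raster(spec)
        assert raster.values.min() >= 1.0
        assert raster.values.max() <= 161.0

    def test_corridor_is_one_connected_band(self):
        spec = LandscapeSpec(n_rows=100, n_cols=100,
                             resistance_range=(50, 161), n_corridors=1,
                             corridor_resistance=1.0, seed=11)
        raster = synthetic.generate_resistance_raster(spec)
        corridor_cells = raster.values == 1.0
        np.testing.assert_array_equal(corridor_cells, raster.corridor_mask)
        labels, n = ndimage.label(corridor_cells, structure=np.ones((3, 3)))
        assert n == 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LandscapeSpec(n_rows=1, n_cols=10)
        with pytest.raises(ValueError):
            LandscapeSpec(resistance_range=(0, 10))
        with pytest.raises(ValueError):
            LandscapeSpec(resistance_range=(5, 161), n_corridors=1,
                          corridor_resistance=10.0)


class TestNodes:
    def test_two_nodes_on_1x3_are_distinct(self):
        raster = make_raster([[1.0, 1.0, 1.0]])
        nodes = synthetic.generate_nodes(raster, 2, seed=0)
        assert len(nodes) == 2
        assert len(nodes[["x", "y"]].drop_duplicates()) == 2

    def test_capacity_error(self):
        raster = make_raster([[1.0, 1.0]])
        with pytest.raises(synthetic.GenerationError):
            synthetic.generate_nodes(raster, 3, seed=0)

    def test_nodes_snap_to_cell_centres(self):
        raster = make_raster(np.ones((5, 5)))
        nodes = synthetic.generate_nodes(raster, 5, seed=2)
        georef = raster.georef
        for node in nodes.itertuples(index=False):
            r, c = georef.cell_of(node.x, node.y)
            assert (node.x, node.y) == georef.cell_center(r, c)

    def test_permeable_cell_strongly_preferred(self):
        """One cell at resistance 1, the other at 1000: selection weight
        1/(1 + 0.001), so the permeable cell wins ~99.9% of draws."""
        raster = make_raster([[1.0, 1000.0]])
        picks = sum(
            synthetic.generate_nodes(raster, 1, seed=s)["x"].iloc[0]
            == raster.georef.cell_center(0, 0)[0]
            for s in range(1000))
        assert picks >= 985  # binomial(1000, 0.999) 5 sd band

    def test_uniform_raster_selection_frequencies_uniform(self):
        raster = make_raster(np.ones((10, 10)))
        counts = np.zeros(100)
        n, reps = 20, 300
        georef = raster.georef
        for s in range(reps):
            nodes = synthetic.generate_nodes(raster, n, seed=s)
            for node in nodes.itertuples(index=False):
                r, c = georef.cell_of(node.x, node.y)
                counts[r * 10 + c] += 1
        p = n / 100
        sd = np.sqrt(reps * p * (1 - p))
        assert np.abs(counts - reps * p).max() < 5 * sd


class TestNetwork:
    def test_collinear_nodes_weights_decrease_with_separation(self):
        raster = make_raster(np.ones((1, 9)))
        georef = raster.georef
        xy = [georef.cell_center(0, c) for c in (0, 4, 8)]
        nodes = pd.DataFrame({"id": [0, 1, 2], "x": [p[0] for p in xy],
                              "y": [p[1] for p in xy]})
        net = synthetic.generate_network(
            nodes, raster, NetworkSpec(n_nodes=3, edge_rule="complete",
                                       weight_decay=0.5, noise_sd=0.0))
        w = net.edges.set_index(
            net.edges.apply(lambda e: (e["node_a"], e["node_b"]), axis=1)
        )["weight"]
        assert w[(0, 1)] > w[(0, 2)]
        assert w[(1, 2)] > w[(0, 2)]

    def test_zero_decay_zero_noise_gives_unit_weights(self):
        raster = make_raster(np.ones((5, 5)))
        nodes = synthetic.generate_nodes(raster, 4, seed=1)
        net = synthetic.generate_network(
            nodes, raster, NetworkSpec(n_nodes=4, weight_decay=0.0,
                                       noise_sd=0.0))
        np.testing.assert_allclose(net.edges["weight"], 1.0)

    def test_deterministic_per_seed(self):
        raster = make_raster(np.random.default_rng(0).uniform(1, 50, (12, 12)))
        nodes = synthetic.generate_nodes(raster, 6, seed=5)
        spec = NetworkSpec(n_nodes=6, noise_sd=0.1, seed=21)
        e1 = synthetic.generate_network(nodes, raster, spec).edges
        e2 = synthetic.generate_network(nodes, raster, spec).edges
        pd.testing.assert_frame_equal(e1, e2)

    def test_gabriel_rule_connected_and_sparser_than_complete(self):
        raster = make_raster(np.ones((20, 20)))
        nodes = synthetic.generate_nodes(raster, 12, seed=3)
        net = synthetic.generate_network(
            nodes, raster, NetworkSpec(n_nodes=12, edge_rule="gabriel"))
        assert net.is_connected()
        assert net.n_edges < 12 * 11 / 2


class TestPolygons:
    def test_mz_k1_covers_the_grid(self):
        georef = GridGeoreference(10, 10, 1200.0, origin=(0.0, 12000.0),
                                  crs_label="synthetic-albers")
        polys, labels = synthetic.generate_polygons(
            pd.DataFrame({"id": [], "x": [], "y": []}), georef, "mz", k=1)
        assert labels == ["I"]
        zone = overlay.rasterize_polygons(polys, georef)
        assert zone.mask.all()

    def test_mz_partition_disjoint_and_exhaustive(self):
        georef = GridGeoreference(9, 12, 1200.0, origin=(0.0, 10800.0),
                                  crs_label="synthetic-albers")
        polys, labels = synthetic.generate_polygons(
            pd.DataFrame({"id": [], "x": [], "y": []}), georef, "mz", k=3)
        masks = [overlay.rasterize_polygons([p], georef, label=lab).mask
                 for p, lab in zip(polys, labels)]
        total = np.zeros(georef.shape, dtype=int)
        for m in masks:
            total += m
        assert np.all(total == 1)

    def test_pac_coverage_near_target(self):
        raster = make_raster(np.ones((40, 40)))
        nodes = synthetic.generate_nodes(raster, 10, seed=9)
        polys, _ = synthetic.generate_polygons(nodes, raster.georef, "pac",
                                               coverage=0.30, seed=1)
        zone = overlay.rasterize_polygons(polys, raster.georef)
        frac = zone.mask.sum() / zone.mask.size
        assert abs(frac - 0.30) <= 0.05

    def test_bad_coverage_rejected(self):
        raster = make_raster(np.ones((5, 5)))
        with pytest.raises(ValueError):
            synthetic.generate_polygons(pd.DataFrame({"id": [0], "x": [0.0],
                                                      "y": [0.0]}),
                                        raster.georef, "pac", coverage=1.5)


class TestLandcover:
    def _grid(self):
        return GridGeoreference(30, 30, 1200.0, origin=(0.0, 36000.0),
                                crs_label="synthetic-albers")

    def test_zero_density_is_all_zero(self):
        for kind in ("cultivation", "canopy"):
            layer = synthetic.generate_landcover(self._grid(), kind,
                                                 patch_density=0.0, seed=0)
            assert not layer.values.any()

    def test_cultivation_is_binary(self):
        layer = synthetic.generate_landcover(self._grid(), "cultivation",
                                             patch_density=0.2, seed=4)
        assert set(np.unique(layer.values)) <= {0.0, 1.0}
        assert layer.values.any()

    def test_canopy_bounded_in_unit_interval(self):
        layer = synthetic.generate_landcover(self._grid(), "canopy",
                                             patch_density=0.3, seed=4)
        assert layer.values.min() >= 0.0
        assert layer.values.max() <= 1.0


class TestFixtureSuite:
    def test_suite_contains_the_named_fixtures(self, fixtures):
        assert {"chain-1x3", "uniform-2x2", "two-component",
                "corridor-50x50"} <= set(fixtures)

    def test_chain_fixture_is_the_series_law_case(self, fixtures):
        fx = fixtures["chain-1x3"]
        np.testing.assert_array_equal(fx.raster.values, [[2.0, 4.0, 6.0]])
        assert fx.expected_resistance == 8.0

    def test_two_component_fixture_declares_infinite_resistance(self, fixtures):
        assert np.isinf(fixtures["two-component"].expected_resistance)

    def test_corridor_fixture_nodes_sit_on_corridor_endpoints(self, corridor):
        fx, net = corridor
        georef = fx.raster.georef
        for node, cell in zip(net.nodes.itertuples(index=False),
                              fx.terminals):
            assert georef.cell_of(node.x, node.y) == cell
            assert fx.corridor_mask[cell]
        assert net.n_edges == 1
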