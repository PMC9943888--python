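"""Impedance module: focal windows vs brute force, resampling arithmetic,
strict threshold rules, action-map partition conservation."""

import numpy as np
import pytest

from circuitpaths import impedance, maps
from circuitpaths.grids import (CumulativeMap, GridGeoreference,
                                LandCoverRaster, ThresholdMask, ZoneMask)


def grid(n_rows, n_cols, cell=1200.0, origin=None, nodata=None):
    origin = origin or (0.0, n_rows * cell)
    return GridGeoreference(n_rows, n_cols, cell, origin=origin,
                            crs_label="synthetic-albers", nodata_mask=nodata)


def brute_force_focal(values, valid, radius_cells):
    """Direct window enumeration: mean over valid cells whose centres lie
    within the radius."""
    n_rows, n_cols = values.shape
    out = np.full(values.shape, np.nan)
    r = int(np.floor(radius_cells))
    for i in range(n_rows):
        for j in range(n_cols):
            acc, cnt = 0.0, 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di * di + dj * dj > radius_cells ** 2:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n_rows and 0 <= jj < n_cols and valid[ii, jj]:
                        acc += values[ii, jj]
                        cnt += 1
            if cnt:
                out[i, j] = acc / cnt
    return out


class TestFocalFraction:
    def test_constant_layers_stay_constant(self):
        g = grid(8, 8)
        for const in (0.0, 1.0):
            layer = LandCoverRaster(g, np.full((8, 8), const))
            out = impedance.focal_fraction(layer, radius_m=3000.0)
            np.testing.assert_allclose(out.values, const)

    def test_single_cell_spreads_as_reciprocal_window_count(self):
        g = grid(9, 9)
        values = np.zeros((9, 9))
        values[4, 4] = 1.0
        out = impedance.focal_fraction(LandCoverRaster(g, values),
                                       radius_m=2500.0)
        oracle = brute_force_focal(values, np.ones((9, 9), bool),
                                   2500.0 / 1200.0)
        np.testing.assert_allclose(out.values, oracle, atol=1e-12)

    def test_matches_brute_force_on_random_scene_with_nodata(self):
        rng = np.random.default_rng(17)
        nodata = rng.random((20, 20)) < 0.1
        g = grid(20, 20, nodata=nodata)
        values = np.where(nodata, np.nan, rng.random((20, 20)))
        out = impedance.focal_fraction(LandCoverRaster(g, values),
                                       radius_m=4000.0)
        oracle = brute_force_focal(np.nan_to_num(values), ~nodata,
                                   4000.0 / 1200.0)
        np.testing.assert_allclose(np.nan_to_num(out.values, nan=-1),
                                   np.nan_to_num(oracle, nan=-1), atol=1e-10)

    def test_output_bounded_by_input_range(self):
        rng = np.random.default_rng(23)
        g = grid(15, 15)
        values = rng.uniform(0.2, 0.7, size=(15, 15))
        out = impedance.focal_fraction(LandCoverRaster(g, values),
                                       radius_m=3600.0)
        assert out.values.min() >= 0.2 - 1e-12
        assert out.values.max() <= 0.7 + 1e-12

    def test_radius_below_cell_size_rejected(self):
        layer = LandCoverRaster(grid(4, 4), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            impedance.focal_fraction(layer, radius_m=600.0)


class TestResample:
    def test_identity_on_matching_grid(self):
        g = grid(6, 6)
        values = np.random.default_rng(0).random((6, 6))
        out = impedance.resample_to_grid(LandCoverRaster(g, values), g)
        np.testing.assert_array_equal(out.values, values)

    def test_block_mean_of_2x2(self):
        src = grid(2, 2, cell=600.0, origin=(0.0, 1200.0))
        tgt = grid(1, 1, cell=1200.0, origin=(0.0, 1200.0))
        layer = LandCoverRaster(src, np.array([[0.0, 0.0], [1.0, 1.0]]))
        out = impedance.resample_to_grid(layer, tgt, method="mean")
        assert out.values[0, 0] == pytest.approx(0.5)

    def test_checkerboard_aggregates_to_half(self):
        src = grid(10, 10, cell=600.0, origin=(0.0, 6000.0))
        tgt = grid(5, 5, cell=1200.0, origin=(0.0, 6000.0))
        checker = np.indices((10, 10)).sum(axis=0) % 2
        out = impedance.resample_to_grid(
            LandCoverRaster(src, checker.astype(float)), tgt, method="mean")
        np.testing.assert_allclose(out.values, 0.5)

    def test_nearest_preserves_binary_values(self):
        src = grid(4, 4, cell=600.0, origin=(0.0, 2400.0))
        tgt = grid(2, 2, cell=1200.0, origin=(0.0, 2400.0))
        binary = np.zeros((4, 4))
        binary[:2, :2] = 1.0
        out = impedance.resample_to_grid(
            LandCoverRaster(src, binary, kind="cultivation"), tgt,
            method="nearest")
        assert set(np.unique(out.values)) <= {0.0, 1.0}
        assert out.values[0, 0] == 1.0

    def test_crs_mismatch_rejected(self):
        src = GridGeoreference(2, 2, 600.0, crs_label="one")
        tgt = GridGeoreference(2, 2, 1200.0, crs_label="two")
        with pytest.raises(Exception, match="CRS"):
            impedance.resample_to_grid(
                LandCoverRaster(src, np.zeros((2, 2))), tgt)


def mz_strips(g, labels):
    """Vertical-strip MZ masks over the grid."""
    masks = []
    width = g.n_cols // len(labels)
    for i, lab in enumerate(labels):
        m = np.zeros(g.shape, bool)
        lo = i * width
        hi = (i + 1) * width if i < len(labels) - 1 else g.n_cols
        m[:, lo:hi] = True
        masks.append(ZoneMask(g, m, label=lab))
    return masks


class TestExceedanceMask:
    def test_uniform_above_threshold_everywhere(self):
        g = grid(6, 6)
        mzs = mz_strips(g, ["I", "II", "IV", "V"])
        frac = LandCoverRaster(g, np.full((6, 6), 0.30))
        out = impedance.exceedance_mask(frac, mzs, impedance.DEFAULT_RULES,
                                        "cultivation")
        assert out.mask.all()

    def test_exactly_at_threshold_is_not_exceeding(self):
        g = grid(6, 6)
        mzs = mz_strips(g, ["I", "II", "IV", "V"])
        frac = LandCoverRaster(g, np.full((6, 6), 0.25))
        out = impedance.exceedance_mask(frac, mzs, impedance.DEFAULT_RULES,
                                        "cultivation")
        assert not out.mask.any()

    def test_canopy_rules_apply_only_in_ruled_zones(self):
        g = grid(6, 8)
        mzs = mz_strips(g, ["I", "II", "IV", "V"])
        frac = LandCoverRaster(g, np.full((6, 8), 0.15))
        out = impedance.exceedance_mask(frac, mzs, impedance.DEFAULT_RULES,
                                        "canopy")
        ruled = mzs[0].mask | mzs[1].mask | mzs[2].mask  # I, II, IV
        np.testing.assert_array_equal(out.mask, ruled)

    def test_mz5_alternative_rule_is_stricter(self):
        g = grid(6, 8)
        mzs = mz_strips(g, ["I", "II", "IV", "V"])
        frac = LandCoverRaster(g, np.full((6, 8), 0.10))
        default = impedance.exceedance_mask(frac, mzs,
                                            impedance.DEFAULT_RULES,
                                            "cultivation")
        alt = impedance.exceedance_mask(frac, mzs,
                                        impedance.ALT_RULES_MZ5_5PCT,
                                        "cultivation")
        assert not default.mask.any()       # 0.10 < 0.25 everywhere
        np.testing.assert_array_equal(alt.mask, mzs[3].mask)  # only MZ V

    def test_lowering_a_threshold_never_removes_cells(self):
        rng = np.random.default_rng(31)
        g = grid(10, 12)
        mzs = mz_strips(g, ["I", "II", "IV", "V"])
        frac = LandCoverRaster(g, rng.random((10, 12)))
        hi = impedance.exceedance_mask(frac, mzs, impedance.DEFAULT_RULES,
                                       "cultivation")
        lo = impedance.exceedance_mask(frac, mzs,
                                       impedance.ALT_RULES_MZ5_5PCT,
                                       "cultivation")
        assert not (hi.mask & ~lo.mask).any()

    def test_overlapping_mz_masks_rejected(self):
        g = grid(4, 4)
        full = ZoneMask(g, np.ones((4, 4), bool), label="I")
        also = ZoneMask(g, np.ones((4, 4), bool), label="II")
        frac = LandCoverRaster(g, np.zeros((4, 4)))
        with pytest.raises(ValueError, match="overlap"):
            impedance.exceedance_mask(frac, [full, also],
                                      impedance.DEFAULT_RULES, "cultivation")

    def test_rule_for_unknown_mz_rejected(self):
        g = grid(4, 4)
        only_one = mz_strips(g, ["I"])
        frac = LandCoverRaster(g, np.zeros((4, 4)))
        with pytest.raises(ValueError, match="unknown MZ"):
            impedance.exceedance_mask(frac, only_one,
                                      impedance.DEFAULT_RULES, "cultivation")


class TestActionMapSummary:
    def test_coincident_masks_area_arithmetic(self):
        g = grid(10, 10)  # 1.44 km2 cells
        m = np.zeros((10, 10), bool)
        m.ravel()[:100][:100] = True
        m[:] = True  # all 100 cells
        exceed = ZoneMask(g, m, "exceed")
        top = ThresholdMask(g, m, 95.0, 0.0)
        pac = ZoneMask(g, m, "pac")
        summary = impedance.action_map_summary(exceed, top, pac)
        t = summary.table.set_index(["status", "pac"])
        assert t.loc[("above", "in_pac"), "area_km2"] == pytest.approx(144.0)
        assert t.loc[("above", "out_pac"), "area_km2"] == 0.0

    def test_empty_exceedance_gives_zero_above(self):
        g = grid(5, 5)
        top = ThresholdMask(g, np.ones((5, 5), bool), 95.0, 0.0)
        summary = impedance.action_map_summary(
            ZoneMask(g, np.zeros((5, 5), bool)), top,
            ZoneMask(g, np.ones((5, 5), bool)))
        assert summary.total_exceedance_km2 == 0.0

    def test_matches_cell_by_cell_classification(self):
        rng = np.random.default_rng(41)
        g = grid(50, 50)
        exceed = rng.random((50, 50)) < 0.3
        top = rng.random((50, 50)) < 0.2
        pac = rng.random((50, 50)) < 0.4
        summary = impedance.action_map_summary(
            ZoneMask(g, exceed), ThresholdMask(g, top, 95.0, 0.0),
            ZoneMask(g, pac))
        t = summary.table.set_index(["status", "pac"])["area_km2"]
        area = g.cell_area_km2
        # exhaustive cell loop oracle
        counts = {("above", "in_pac"): 0, ("above", "out_pac"): 0,
                  ("below", "in_pac"): 0, ("below", "out_pac"): 0}
        for i in range(50):
            for j in range(50):
                if not top[i, j]:
                    continue
                key = ("above" if exceed[i, j] else "below",
                       "in_pac" if pac[i, j] else "out_pac")
                counts[key] += 1
        for key, n in counts.items():
            assert t.loc[key] == pytest.approx(n * area)
        # partition conservation
        assert t.sum() == pytest.approx(top.sum() * area)

    def test_hectares_are_100x_km2(self):
        rng = np.random.default_rng(43)
        g = grid(8, 8)
        summary = impedance.action_map_summary(
            ZoneMask(g, rng.random((8, 8)) < 0.5),
            ThresholdMask(g, rng.random((8, 8)) < 0.5, 95.0, 0.0),
            ZoneMask(g, rng.random((8, 8)) < 0.5))
        np.testing.assert_allclose(summary.table["area_ha"],
                                   100.0 * summary.table["area_km2"])
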