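"""Land-cover impedance thresholds and spatial action maps.

Cultivation and woodland canopy fractions are computed in a circular
moving window (6.44 km radius by default), resampled to the analysis
grid, and compared against per-management-zone thresholds beyond which
functional connectivity is known to degrade. Intersecting the exceedance
cells with the top-connectivity mask, split inside/outside PACs, yields
the action map: where to intervene (e.g. conifer removal, cultivation
easements) for the greatest connectivity return.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (CRSMismatchError, GridAlignmentError, GridGeoreference,
                    LandCoverRaster, ThresholdMask, ZoneMask)

__all__ = [
    "ThresholdRule",
    "ThresholdRuleSet",
    "DEFAULT_RULES",
    "ALT_RULES_MZ5_5PCT",
    "focal_fraction",
    "resample_to_grid",
    "exceedance_mask",
    "action_map_summary",
]

FOCAL_RADIUS_M = 6440.0  # 6.44 km moving-window radius


@dataclass(frozen=True)
class ThresholdRule:
    landcover: str   # {"cultivation", "canopy"}
    mz: str          # management-zone label
    threshold: float  # exceedance is strict: fraction > threshold

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ThresholdRuleSet:
    name: str
    rules: tuple[ThresholdRule, ...]

    def for_landcover(self, kind: str) -> dict[str, float]:
        return {r.mz: r.threshold for r in self.rules if r.landcover == kind}


def _ruleset(name, entries):
    return ThresholdRuleSet(name, tuple(ThresholdRule(*e) for e in entries))


# cultivation > 25% in MZs I, II, IV and V; canopy > 10% in MZs I, II, IV
DEFAULT_RULES = _ruleset("cultivation25-all", [
    ("cultivation", "I", 0.25), ("cultivation", "II", 0.25),
    ("cultivation", "IV", 0.25), ("cultivation", "V", 0.25),
    ("canopy", "I", 0.10), ("canopy", "II", 0.10), ("canopy", "IV", 0.10),
])

# alternative convention: cultivation > 5% in MZ V
ALT_RULES_MZ5_5PCT = _ruleset("cultivation5-mzV", [
    ("cultivation", "I", 0.25), ("cultivation", "II", 0.25),
    ("cultivation", "IV", 0.25), ("cultivation", "V", 0.05),
    ("canopy", "I", 0.10), ("canopy", "II", 0.10), ("canopy", "IV", 0.10),
])

RULE_SETS = {r.name: r for r in (DEFAULT_RULES, ALT_RULES_MZ5_5PCT)}


def _disk_footprint(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return (dx * dx + dy * dy) <= radius_cells * radius_cells


def focal_fraction(layer: LandCoverRaster,
                   radius_m: float = FOCAL_RADIUS_M) -> LandCoverRaster:
    """Circular moving-window mean of a land-cover layer.

    The window covers every cell whose centre lies within ``radius_m`` of
    the focal cell centre. At raster edges and next to nodata the window
    truncates: the mean is over the available valid cells only (no
    padding), so edge fractions are not biased toward zero. A window with
    zero valid cells yields nodata.
    """
    georef = layer.georef
    if radius_m < georef.cell_size:
        raise ValueError("window radius must be at least one cell size")
    foot = _disk_footprint(radius_m / georef.cell_size)
    valid = georef.valid_mask() & np.isfinite(layer.values)
    vals = np.where(valid, layer.values, 0.0)
    sums = ndimage.convolve(vals, foot.astype(float),
                            mode="constant", cval=0.0)
    counts = ndimage.convolve(valid.astype(float), foot.astype(float),
                              mode="constant", cval=0.0)
    counts_int = np.rint(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts_int > 0, sums / counts, np.nan)
    frac = np.clip(frac, 0.0, 1.0, where=np.isfinite(frac), out=frac)
    nodata = ~(counts_int > 0)
    out_georef = georef.with_nodata(nodata if nodata.any() else None)
    return LandCoverRaster(out_georef, np.where(nodata, np.nan, frac),
                           kind="fraction")


def resample_to_grid(layer: LandCoverRaster, target: GridGeoreference,
                     method: str = "mean") -> LandCoverRaster:
    """Resample a layer onto the analysis grid.

    ``mean`` (default, for fractions) bins each source cell centre into
    the target cell containing it and averages; ``nearest`` (for
    categorical layers) samples the source cell containing each target
    cell centre. Both grids must be in the same CRS — no reprojection.
    """
    src = layer.georef
    if src.crs_label != target.crs_label:
        raise CRSMismatchError(
            f"layer CRS {src.crs_label!r} != target CRS {target.crs_label!r}")
    if src.same_grid(target):
        return LandCoverRaster(target.with_nodata(src.nodata_mask),
                               layer.values.copy(), kind=layer.kind)

    valid = src.valid_mask() & np.isfinite(layer.values)
    if method == "mean":
        xs, ys = src.cell_centers()
        tx0, ty0 = target.origin
        cols = np.floor((xs - tx0) / target.cell_size).astype(int)
        rows = np.floor((ty0 - ys) / target.cell_size).astype(int)
        inside = ((rows >= 0) & (rows < target.n_rows)
                  & (cols >= 0) & (cols < target.n_cols) & valid)
        flat = rows[inside] * target.n_cols + cols[inside]
        sums = np.bincount(flat, weights=layer.values[inside],
                           minlength=target.n_rows * target.n_cols)
        counts = np.bincount(flat, minlength=target.n_rows * target.n_cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(counts > 0, sums / counts, np.nan)
        out = out.reshape(target.shape)
        nodata = counts.reshape(target.shape) == 0
        kind = "fraction"
    elif method == "nearest":
        xs, ys = target.cell_centers()
        sx0, sy0 = src.origin
        cols = np.floor((xs - sx0) / src.cell_size).astype(int)
        rows = np.floor((sy0 - ys) / src.cell_size).astype(int)
        inside = ((rows >= 0) & (rows < src.n_rows)
                  & (cols >= 0) & (cols < src.n_cols))
        out = np.full(target.shape, np.nan)
        out[inside] = layer.values[rows[inside], cols[inside]]
        nodata = ~np.isfinite(out)
        kind = layer.kind
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    georef = target.with_nodata(nodata if nodata.any() else None)
    return LandCoverRaster(georef, out, kind=kind)


def exceedance_mask(fraction: LandCoverRaster, mz_masks: Sequence[ZoneMask],
                    rules: ThresholdRuleSet, landcover: str) -> ZoneMask:
    """Cells whose land-cover fraction strictly exceeds their zone's rule.

    A cell is marked iff its management zone has a rule for this land-cover
    kind and the fraction is strictly greater than the rule's threshold
    (the "greater than" convention: a cell exactly at the threshold is
    not exceeding). Cells in zones without a rule are False. Overlapping
    MZ masks are rejected.
    """
    georef = fraction.georef
    counts = np.zeros(georef.shape, dtype=int)
    for mz in mz_masks:
        georef.require_same_grid(mz.georef, "fraction and MZ masks")
        counts += mz.mask.astype(int)
    if np.any(counts > 1):
        raise ValueError("MZ masks overlap; zone assignment is ambiguous")
    per_mz = rules.for_landcover(landcover)
    known = {m.label for m in mz_masks}
    missing = set(per_mz) - known
    if missing:
        raise ValueError(f"rules reference unknown MZ labels: {sorted(missing)}")
    out = np.zeros(georef.shape, dtype=bool)
    finite = np.isfinite(fraction.values) & georef.valid_mask()
    for mz in mz_masks:
        thr = per_mz.get(mz.label)
        if thr is None:
            continue
        out |= mz.mask & finite & (fraction.values > thr)
    return ZoneMask(georef, out, label=f"exceed:{landcover}:{rules.name}")


@dataclass
class ActionMapSummary:
    """Areas above/below an impedance threshold within the top-connectivity
    mask, split inside/outside PACs. Areas in km2 with ha twins (x100)."""

    landcover: str
    table: pd.DataFrame  # rows: above/below x in/out PAC

    @property
    def total_exceedance_km2(self) -> float:
        t = self.table
        return float(t.loc[t["status"] == "above", "area_km2"].sum())


def action_map_summary(exceedance: ZoneMask, top_mask: ThresholdMask,
                       pac: ZoneMask, landcover: str = "") -> ActionMapSummary:
    """Partition the top-connectivity mask by threshold exceedance and PAC
    membership.

    Every top-connectivity cell falls in exactly one of four classes
    (above/below threshold x in/out PAC); the four areas sum to the
    top-mask area exactly.
    """
    georef = top_mask.georef
    georef.require_same_grid(exceedance.georef, "exceedance and top mask")
    georef.require_same_grid(pac.georef, "PAC and top mask")
    valid = georef.valid_mask()
    top = top_mask.mask & valid
    area = georef.cell_area_km2
    rows = []
    for status, emask in (("above", exceedance.mask), ("below", ~exceedance.mask)):
        for where, pmask in (("in_pac", pac.mask), ("out_pac", ~pac.mask)):
            n = int(np.count_nonzero(top & emask & pmask))
            rows.append((status, where, n * area, n * area * 100.0))
    table = pd.DataFrame(rows, columns=["status", "pac", "area_km2", "area_ha"])
    return ActionMapSummary(landcover, table)


def action_class_grid(exceedance: ZoneMask, top_mask: ThresholdMask) -> np.ndarray:
    """Class raster: 0 = not top-connectivity, 1 = top below threshold,
    2 = top exceeding threshold."""
    out = np.zeros(top_mask.georef.shape, dtype=np.int8)
    top = top_mask.mask & top_mask.georef.valid_mask()
    out[top] = 1
    out[top & exceedance.mask] = 2
    return out
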