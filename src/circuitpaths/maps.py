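"""Cumulative connectivity maps, percentile thresholding, pathway delineation.

Summing the per-pair current maps over every network edge yields the
cumulative connectivity map — the single surface that downstream
prioritization thresholds and overlays. Percentile thresholds use the
linear-interpolation quantile over all valid cells (zeros included by
default) and the >= rule at the threshold, so masks are reproducible and
conservative (ties fall inside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circuit import PairSolution
from .grids import CumulativeMap, GridGeoreference, ThresholdMask

__all__ = [
    "DEFAULT_THRESHOLD_LEVELS",
    "PATHWAY_LEVELS",
    "PathwayMask",
    "accumulate_currents",
    "percentile_threshold",
    "threshold_series",
    "delineate_pathway",
]

logger = logging.getLogger(__name__)

# 50th..95th by 5, plus the 99th
DEFAULT_THRESHOLD_LEVELS: tuple[float, ...] = tuple(range(50, 100, 5)) + (99,)
# per-edge pathway delineation levels
PATHWAY_LEVELS: tuple[float, ...] = (99.0, 99.5, 99.75)


class EmptyMapError(ValueError):
    """Map contains no valid cells to threshold."""


def accumulate_currents(solutions) -> CumulativeMap:
    """Cell-wise sum of pairwise current maps.

    Accepts any iterable/stream of :class:`PairSolution`; infinite-resistance
    solutions contribute their all-zero maps. All solutions must share one
    georeference.
    """
    total = None
    georef: GridGeoreference | None = None
    n = 0
    for sol in solutions:
        if georef is None:
            georef = sol.georef
            total = np.zeros(georef.shape)
        elif not georef.same_grid(sol.georef):
            raise ValueError("current maps are not on the same grid "
                             f"(edge {sol.edge_id!r})")
        total += sol.current_map
        n += 1
    if georef is None:
        raise ValueError("no solutions to accumulate")
    return CumulativeMap(georef, total, n_pairs_summed=n)


def _percentile_value(values: np.ndarray, georef: GridGeoreference,
                      level: float, include_zeros: bool) -> float:
    valid = georef.valid_mask() & np.isfinite(values)
    pool = values[valid]
    if not include_zeros:
        pool = pool[pool > 0]
    if pool.size == 0:
        raise EmptyMapError("no valid cells to take a percentile over")
    return float(np.percentile(pool, level))  # linear-interpolation quantile


def percentile_threshold(cmap: CumulativeMap, level: float,
                         include_zeros: bool = True) -> ThresholdMask:
    """Mask of cells at or above the level-th percentile of the map.

    ``include_zeros=False`` restricts the percentile base to cells with
    positive connectivity (an alternative convention; the default uses
    every valid cell).
    """
    if not 0 < level < 100:
        raise ValueError("percentile level must lie in (0, 100)")
    thr = _percentile_value(cmap.values, cmap.georef, level, include_zeros)
    mask = (cmap.values >= thr) & cmap.georef.valid_mask()
    return ThresholdMask(cmap.georef, mask, percentile_level=level,
                         threshold_value=thr)


def threshold_series(cmap: CumulativeMap,
                     levels=DEFAULT_THRESHOLD_LEVELS,
                     include_zeros: bool = True) -> list[ThresholdMask]:
    """Threshold masks for an ascending series of percentile levels."""
    levels = sorted(levels)
    masks = [percentile_threshold(cmap, lv, include_zeros) for lv in levels]
    areas = [m.area_km2 for m in masks]
    assert all(a >= b for a, b in zip(areas, areas[1:])), \
        "threshold areas must be non-increasing with level"
    return masks


@dataclass
class PathwayMask:
    """Per-edge pathway delineation at nested percentile levels."""

    edge_id: object
    georef: GridGeoreference
    masks: dict[float, np.ndarray]  # level -> boolean grid
    rank: int | None = None

    def __post_init__(self) -> None:
        levels = sorted(self.masks)
        for lo, hi in zip(levels, levels[1:]):
            if np.any(self.masks[hi] & ~self.masks[lo]):
                raise ValueError("pathway masks must be nested by level")

    def mask_at(self, level: float) -> np.ndarray:
        return self.masks[level]


def delineate_pathway(solution: PairSolution,
                      levels=PATHWAY_LEVELS,
                      rank: int | None = None) -> PathwayMask:
    """Threshold one edge's own current map at the delineation levels.

    Percentiles are taken over the edge's own current-map distribution
    (valid cells), not the cumulative map's. An infinite-resistance
    solution yields empty masks with a warning.
    """
    georef = solution.georef
    if not solution.is_finite:
        logger.warning("edge %r is disconnected; pathway masks are empty",
                       solution.edge_id)
        empty = {lv: np.zeros(georef.shape, dtype=bool) for lv in levels}
        return PathwayMask(solution.edge_id, georef, empty, rank=rank)
    masks = {}
    for lv in levels:
        thr = _percentile_value(solution.current_map, georef, lv,
                                include_zeros=True)
        masks[lv] = (solution.current_map >= thr) & georef.valid_mask()
    return PathwayMask(solution.edge_id, georef, masks, rank=rank)
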