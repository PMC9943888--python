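"""Grid georeferencing and raster containers.

All rasters in the package share one lightweight georeference model: a
regular grid of square cells in a projected CRS, addressed by (row, col)
with row 0 at the top (north). Cell (r, c) has its centre at

    x = origin_x + (c + 0.5) * cell_size
    y = origin_y - (r + 0.5) * cell_size

where ``origin`` is the upper-left corner of the upper-left cell. This is
the ESRI ASCII grid / GeoTIFF north-up convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GridGeoreference",
    "ResistanceRaster",
    "CumulativeMap",
    "LandCoverRaster",
    "ZoneMask",
    "ThresholdMask",
]


class GridAlignmentError(ValueError):
    """Two grids that must share a georeference do not."""


class CRSMismatchError(ValueError):
    """Inputs are in different coordinate reference systems."""


@dataclass(frozen=True)
class GridGeoreference:
    """Geometry of a north-up square-cell analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; both must be positive.
    cell_size : float
        Cell edge length in metres (> 0). The reference analysis uses a
        1200 m grid, i.e. 1.44 km^2 per cell.
    origin : (float, float)
        Projected (x, y) of the upper-left corner of the grid.
    crs_label : str
        Free-text CRS tag (e.g. an Albers Equal Area Conic label). Grids
        are only combined when labels match; no reprojection is attempted.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data. Defaults to all-valid.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local-projected"
    nodata_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have positive dimensions")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata_mask is not None:
            mask = np.asarray(self.nodata_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("nodata_mask shape does not match grid")
            object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.n_rows * self.cell_size,
                x0 + self.n_cols * self.cell_size, y0)

    def valid_mask(self) -> np.ndarray:
        if self.nodata_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.nodata_mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (x, y) centre-coordinate grids, each of shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing point (x, y).

        Points exactly on a cell boundary resolve toward the lower row,
        then lower column index (deterministic snapping rule).
        """
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        # boundary ties: a point on the shared edge belongs to the
        # lower-index cell
        if (x - x0) / self.cell_size == col and col > 0:
            col -= 1
        if (y0 - y) / self.cell_size == row and row > 0:
            row -= 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def same_grid(self, other: "GridGeoreference", *, atol: float = 1e-6) -> bool:
        """Geometric equality, ignoring nodata masks."""
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
            and self.crs_label == other.crs_label
        )

    def require_same_grid(self, other: "GridGeoreference", what: str = "rasters") -> None:
        if self.crs_label != other.crs_label:
            raise CRSMismatchError(
                f"{what} are in different CRS ({self.crs_label!r} vs {other.crs_label!r})"
            )
        if not self.same_grid(other):
            raise GridAlignmentError(f"{what} are not on the same grid")

    def with_nodata(self, mask: Optional[np.ndarray]) -> "GridGeoreference":
        return replace(self, nodata_mask=mask)


def _check_values(georef: GridGeoreference, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != georef.shape:
        raise ValueError("raster values do not match the georeference shape")
    return values


@dataclass
class ResistanceRaster:
    """Per-cell positive resistance to gene flow."""

    georef: GridGeoreference
    values: np.ndarray
    corridor_mask: Optional[np.ndarray] = None  # set by the synthetic generator

    def __post_init__(self) -> None:
        self.values = _check_values(self.georef, self.values)
        valid = self.georef.valid_mask()
        v = self.values[valid]
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError("resistance values must be positive and finite")


@dataclass
class CumulativeMap:
    """Cell-wise sum of pairwise current maps."""

    georef: GridGeoreference
    values: np.ndarray
    n_pairs_summed: int = 0

    def __post_init__(self) -> None:
        self.values = _check_values(self.georef, self.values)
        valid = self.georef.valid_mask()
        if self.values[valid].size and np.any(self.values[valid] < 0):
            raise ValueError("cumulative connectivity must be non-negative")


@dataclass
class LandCoverRaster:
    """Binary (cultivation) or fractional [0, 1] (canopy) land-cover layer."""

    georef: GridGeoreference
    values: np.ndarray
    kind: str = "fraction"  # {"cultivation", "canopy", "fraction"}

    def __post_init__(self) -> None:
        self.values = _check_values(self.georef, self.values)
        valid = self.georef.valid_mask()
        v = self.values[valid]
        if self.kind == "cultivation":
            if v.size and not np.all(np.isin(v, (0.0, 1.0))):
                raise ValueError("cultivation layer must be binary 0/1")
        elif v.size and (np.any(v < 0) or np.any(v > 1)):
            raise ValueError("fraction layer must lie in [0, 1]")


@dataclass
class ZoneMask:
    """Boolean membership grid for a polygon set (PACs, one MZ, custom)."""

    georef: GridGeoreference
    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.georef.shape:
            raise ValueError("zone mask shape does not match grid")
        self.mask = mask

    @property
    def area_km2(self) -> float:
        return float(np.count_nonzero(self.mask & self.georef.valid_mask())
                     * self.georef.cell_area_km2)


@dataclass
class ThresholdMask:
    """Cells at or above a percentile threshold of a cumulative map."""

    georef: GridGeoreference
    mask: np.ndarray
    percentile_level: float
    threshold_value: float
    area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.georef.shape:
            raise ValueError("threshold mask shape does not match grid")
        self.mask = mask
        self.area_km2 = float(
            np.count_nonzero(mask & self.georef.valid_mask())
            * self.georef.cell_area_km2
        )
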