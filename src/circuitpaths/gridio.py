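"""Text-format I/O: ESRI ASCII grids, GeoJSON polygon sets, CSV tables.

Rasters travel as ESRI ASCII grids (.asc) — a plain-text header of six
key/value lines followed by whitespace-separated cell values, row-major
from the north-west corner. The CRS label is carried in a sidecar-free
way: a comment is not legal in .asc, so the label is supplied by the
caller on read and defaulted on write.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import GridGeoreference

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_polygons_geojson",
    "write_polygons_geojson",
    "read_node_table",
    "write_node_table",
    "read_edge_table",
    "write_edge_table",
]

_NODATA_DEFAULT = -9999.0


def write_ascii_grid(path: str | Path, georef: GridGeoreference,
                     values: np.ndarray, nodata_value: float = _NODATA_DEFAULT) -> None:
    """Write a single-band raster as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != georef.shape:
        raise ValueError("values shape does not match georeference")
    out = values.copy()
    if georef.nodata_mask is not None:
        out[georef.nodata_mask] = nodata_value
    x0, y0 = georef.origin
    yll = y0 - georef.n_rows * georef.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {georef.n_cols}\n")
        fh.write(f"nrows {georef.n_rows}\n")
        fh.write(f"xllcorner {float(x0)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(georef.cell_size)!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path,
                    crs_label: str = "local-projected") -> tuple[GridGeoreference, np.ndarray]:
    """Read an ESRI ASCII grid; returns (georef, values) with NaN at nodata."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.asarray(parts, dtype=float))
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"ASCII grid missing header field {required!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    values = np.concatenate(rows) if rows else np.empty(0)
    if values.size != n_rows * n_cols:
        raise ValueError("ASCII grid body does not match declared shape")
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value")
    mask = None
    if nodata is not None:
        mask = values == nodata
        values = np.where(mask, np.nan, values)
        if not mask.any():
            mask = None
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * header["cellsize"])
    georef = GridGeoreference(n_rows, n_cols, header["cellsize"], origin,
                              crs_label=crs_label, nodata_mask=mask)
    return georef, values


def write_polygons_geojson(path: str | Path, polygons: Sequence[BaseGeometry],
                           labels: Optional[Sequence[str]] = None,
                           crs_label: str = "local-projected") -> None:
    features = []
    for i, geom in enumerate(polygons):
        props = {"label": labels[i] if labels is not None else str(i)}
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(geom)})
    doc = {"type": "FeatureCollection", "crs_label": crs_label, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_polygons_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[str], str]:
    """Returns (geometries, labels, crs_label)."""
    doc = json.loads(Path(path).read_text())
    geoms, labels = [], []
    for i, feat in enumerate(doc.get("features", [])):
        geoms.append(shape(feat["geometry"]))
        labels.append(str(feat.get("properties", {}).get("label", i)))
    return geoms, labels, doc.get("crs_label", "local-projected")


def write_node_table(path: str | Path, nodes: pd.DataFrame) -> None:
    nodes[["id", "x", "y"]].to_csv(path, index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    return df


def write_edge_table(path: str | Path, edges: pd.DataFrame) -> None:
    cols = ["id", "node_a", "node_b", "weight"]
    if "betweenness" in edges.columns:
        cols.append("betweenness")
    edges[cols].to_csv(path, index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "node_a", "node_b", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    return df
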