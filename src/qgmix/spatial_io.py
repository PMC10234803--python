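"""Plain-text spatial formats: ESRI ASCII grids and GeoJSON features.

Grids are square-celled rasters with a lower-left origin; internally the
array is stored south-up (row 0 = southernmost row) and flipped on ESRI
ASCII write/read, which stores rows north to south.  Sources are GeoJSON
Point features with ``source_id``, ``chemical``, ``year`` and ``mass_lb``
properties; roads are two-point LineString features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

NODATA = -9999.0


@dataclass
class Grid:
    """Regular square-celled raster on a planar (km) coordinate system."""

    values: np.ndarray      # (nrows, ncols), row 0 = southernmost
    xll: float              # x of the lower-left corner of the grid
    yll: float
    cellsize: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return (
            self.xll,
            self.xll + nx * self.cellsize,
            self.yll,
            self.yll + ny * self.cellsize,
        )

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Column/row of the cell containing each point.

        Membership is half-open [edge, next edge) in both axes, so a point
        on an interior edge belongs to the higher-index cell.  Indices may
        fall outside the grid; callers check bounds.
        """
        col = np.floor((np.asarray(x, float) - self.xll) / self.cellsize).astype(int)
        row = np.floor((np.asarray(y, float) - self.yll) / self.cellsize).astype(int)
        return col, row


def write_esri_ascii(grid: Grid, path: str | Path) -> None:
    ny, nx = grid.values.shape
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {grid.xll}\n"
        f"yllcorner {grid.yll}\n"
        f"cellsize {grid.cellsize}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = np.flipud(grid.values)    # ESRI ASCII rows run north -> south
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.8g")


def read_esri_ascii(path: str | Path) -> Grid:
    with open(path) as fh:
        hdr = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                hdr[key] = float(val)
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    body = body.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    values = np.flipud(body)
    if "nodata_value" in hdr:
        values = np.where(values == hdr["nodata_value"], np.nan, values)
    return Grid(
        values=values,
        xll=hdr["xllcorner"],
        yll=hdr["yllcorner"],
        cellsize=hdr["cellsize"],
    )


def write_sources_geojson(sources: pd.DataFrame, path: str | Path) -> None:
    """Sources table (source_id, x, y, chemical, year, mass_lb) -> GeoJSON."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {
                "source_id": int(row.source_id),
                "chemical": row.chemical,
                "year": int(row.year),
                "mass_lb": float(row.mass_lb),
            },
        }
        for row in sources.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_sources_geojson(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        x, y = feat["geometry"]["coordinates"]
        rows.append({"x": x, "y": y, **feat["properties"]})
    return pd.DataFrame(rows)


def write_roads_geojson(roads: pd.DataFrame, path: str | Path) -> None:
    """Roads table (segment_id, x1, y1, x2, y2) -> GeoJSON LineStrings."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[row.x1, row.y1], [row.x2, row.y2]],
            },
            "properties": {"segment_id": int(row.segment_id)},
        }
        for row in roads.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_roads_geojson(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        (x1, y1), (x2, y2) = feat["geometry"]["coordinates"][0], feat[
            "geometry"
        ]["coordinates"][-1]
        rows.append(
            {
                "segment_id": feat["properties"].get("segment_id", len(rows)),
                "x1": x1,
                "y1": y1,
                "x2": x2,
                "y2": y2,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["length"] = np.hypot(df.x2 - df.x1, df.y2 - df.y1)
    return df
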