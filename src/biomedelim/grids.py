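"""Grid, raster, polygon and point primitives shared by the whole pipeline.

Rasters are kept as plain 2-D float arrays on an explicit :class:`GridSpec`;
no-data is ``NaN`` in memory and an integer sentinel on disk.  On-disk formats
are deliberately text based: ESRI ASCII grid for rasters (with a ``.prj``
sidecar holding the CRS identifier) and GeoJSON for polygons.

Conventions
-----------
* Cell indexing is row-major from the top-left corner; cell ``(r, c)`` has its
  center at ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
* Points on a polygon boundary count as inside (closed-set rule), both in
  rasterization and point-in-polygon queries.
* A CRS id starting with ``"ea-km"`` declares a projected equal-area grid with
  map units of kilometres, so areas are exact cell counts times ``cell_size**2``.
  ``"EPSG:4326"`` (or any id starting with ``"geographic"``) declares
  longitude/latitude degrees and triggers the spherical-band area formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "GridSpec",
    "RasterLayer",
    "BinaryMap",
    "PolygonSet",
    "LabelledPoint",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
    "read_points",
    "write_points",
    "rasterize_polygons",
    "equal_area_km2",
    "sample_layer",
    "haversine_km",
]


class CRSMismatchError(ValueError):
    """Raised when two geodata objects carry different CRS identifiers."""


def is_geographic(crs_id: str) -> bool:
    c = crs_id.strip().lower()
    return c in {"epsg:4326", "wgs84"} or c.startswith("geographic")


def is_equal_area_km(crs_id: str) -> bool:
    return crs_id.strip().lower().startswith("ea-km")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: shape, top-left origin, square cell size, CRS."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float
    crs_id: str = "ea-km"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned(self, other: "GridSpec") -> bool:
        return self == other

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        return (
            self.origin_x + (c + 0.5) * self.cell_size,
            self.origin_y - (r + 0.5) * self.cell_size,
        )

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays of the x and y coordinates of every cell center."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell index containing (x, y), or None when outside the extent."""
        c = int(math.floor((x - self.origin_x) / self.cell_size))
        r = int(math.floor((self.origin_y - y) / self.cell_size))
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return (r, c)
        return None

    def points_to_cells(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized point→cell lookup: (rows, cols, inside_mask)."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        cc = np.floor((xs - self.origin_x) / self.cell_size).astype(int)
        rr = np.floor((self.origin_y - ys) / self.cell_size).astype(int)
        inside = (rr >= 0) & (rr < self.n_rows) & (cc >= 0) & (cc < self.n_cols)
        return rr, cc, inside


@dataclass
class RasterLayer:
    """A single-band raster: values on a GridSpec, NaN marks no-data."""

    grid: GridSpec
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_nodata(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class BinaryMap:
    """A {0, 1, no-data} raster; no-data is NaN."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("value array shape does not match grid")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("binary map cells must be 0, 1 or no-data")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def ones(self) -> np.ndarray:
        return self.values == 1.0

    def complement(self) -> "BinaryMap":
        vals = np.where(np.isnan(self.values), np.nan, 1.0 - self.values)
        return BinaryMap(self.grid, vals)

    def as_layer(self, name: str = "binary") -> RasterLayer:
        return RasterLayer(self.grid, self.values.copy(), name)


@dataclass
class PolygonSet:
    """A collection of (multi)polygons sharing one CRS."""

    polygons: list[BaseGeometry]
    crs_id: str = "ea-km"

    def __post_init__(self) -> None:
        repaired = []
        for g in self.polygons:
            if not g.is_valid:
                g = shapely.make_valid(g)
            repaired.append(g)
        self.polygons = repaired
        self._union: BaseGeometry | None = None

    def union(self) -> BaseGeometry:
        if self._union is None:
            self._union = unary_union(self.polygons) if self.polygons else shapely.Polygon()
        return self._union

    def covers_xy(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Closed-set point-in-polygon test (boundary counts as inside)."""
        geom = self.union()
        if geom.is_empty:
            return np.zeros(np.shape(xs), dtype=bool)
        shapely.prepare(geom)
        return shapely.intersects_xy(geom, xs, ys)


@dataclass(frozen=True)
class LabelledPoint:
    """A point with a text label (biome name, species name, 'presence', ...)."""

    x: float
    y: float
    label: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("point coordinates must be finite")


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid with a .prj sidecar, GeoJSON, CSV points
# ---------------------------------------------------------------------------

_DISK_NODATA = -9999.0


def write_raster(layer: RasterLayer, path: str | Path, nodata: float = _DISK_NODATA) -> Path:
    """Write a layer as an ESRI ASCII grid; the CRS id goes to a .prj sidecar."""
    path = Path(path)
    g = layer.grid
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    if np.any(layer.values == nodata):
        raise ValueError(f"no-data marker {nodata} collides with a legitimate value")
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    path.with_suffix(".prj").write_text(g.crs_id + "\n")
    return path


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
                header[key.lower()] = float(val)
            except ValueError as exc:
                raise ValueError(f"malformed ASCII-grid header line: {line!r}") from exc
        vals = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(
            f"data shape {vals.shape} disagrees with header ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", _DISK_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    cell = header["cellsize"]
    prj = path.with_suffix(".prj")
    crs_id = prj.read_text().strip() if prj.exists() else "unknown"
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        crs_id=crs_id,
    )
    return RasterLayer(grid, vals, name or path.stem)


def write_polygons(polys: PolygonSet, path: str | Path) -> Path:
    path = Path(path)
    features = [
        {"type": "Feature", "properties": {}, "geometry": mapping(g)}
        for g in polys.polygons
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": polys.crs_id}},
        "features": features,
    }
    path.write_text(json.dumps(doc))
    return path


def read_polygons(path: str | Path) -> PolygonSet:
    doc = json.loads(Path(path).read_text())
    crs_id = doc.get("crs", {}).get("properties", {}).get("name", "unknown")
    geoms = [shape(f["geometry"]) for f in doc.get("features", [])]
    return PolygonSet(geoms, crs_id)


def write_points(points: Sequence[LabelledPoint], path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {"x": [p.x for p in points], "y": [p.y for p in points], "label": [p.label for p in points]}
    ).to_csv(path, index=False)
    return path


def read_points(path: str | Path) -> list[LabelledPoint]:
    import pandas as pd

    df = pd.read_csv(path)
    return [LabelledPoint(float(r.x), float(r.y), str(r.label)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Rasterization, sampling and area
# ---------------------------------------------------------------------------


def rasterize_polygons(polys: PolygonSet, grid: GridSpec) -> BinaryMap:
    """Burn polygons onto a grid with the cell-center containment rule.

    A cell is 1 iff its center lies inside (or on the boundary of) any
    polygon.  Raises :class:`CRSMismatchError` rather than reprojecting.
    """
    if polys.crs_id != grid.crs_id:
        raise CRSMismatchError(
            f"polygon CRS {polys.crs_id!r} != grid CRS {grid.crs_id!r}"
        )
    xs, ys = grid.center_coords()
    inside = polys.covers_xy(xs.ravel(), ys.ravel()).reshape(grid.shape)
    return BinaryMap(grid, inside.astype(float))


def sample_layer(layer: RasterLayer, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Layer values at point locations; NaN outside the extent or on no-data."""
    rr, cc, inside = layer.grid.points_to_cells(np.asarray(xs), np.asarray(ys))
    out = np.full(rr.shape, np.nan)
    out[inside] = layer.values[rr[inside], cc[inside]]
    return out


def _geographic_cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Per-row cell areas on the sphere: R^2 * dlon * (sin(top) - sin(bottom))."""
    lat_top = grid.origin_y - np.arange(grid.n_rows) * grid.cell_size
    lat_bot = lat_top - grid.cell_size
    dlon = math.radians(grid.cell_size)
    band = (
        EARTH_RADIUS_KM**2
        * dlon
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )
    return np.repeat(band[:, None], grid.n_cols, axis=1)


def cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Per-cell area in km² for a declared equal-area or geographic grid."""
    if is_equal_area_km(grid.crs_id):
        return np.full(grid.shape, grid.cell_size**2)
    if is_geographic(grid.crs_id):
        return _geographic_cell_areas_km2(grid)
    raise ValueError(
        f"cannot compute areas for CRS {grid.crs_id!r}; declare an 'ea-km' "
        "equal-area grid or a geographic CRS"
    )


def equal_area_km2(bmap: BinaryMap) -> tuple[float, float]:
    """Area of the 1-cells in km² and their fraction of all valid cells."""
    areas = cell_areas_km2(bmap.grid)
    valid = bmap.valid
    if not valid.any():
        raise ValueError("map has no valid cells")
    area_ones = float(areas[bmap.ones].sum())
    area_all = float(areas[valid].sum())
    return area_ones, area_ones / area_all


def haversine_km(x1: float, y1: float, x2: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1 = math.radians(x1), math.radians(y1)
    lon2 = np.radians(np.asarray(x2, dtype=float))
    lat2 = np.radians(np.asarray(y2, dtype=float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + math.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
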