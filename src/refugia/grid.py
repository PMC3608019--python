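"""Georeferenced grids, rasters and raster stacks.

Rasters are plain 2-D float arrays (row 0 = northernmost row) carried
alongside a :class:`GridSpec`; ``NaN`` marks nodata.  On-disk format is the
ESRI ASCII grid (``.asc``), a text format every GIS reads.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid. ``origin_lon``/``origin_lat`` is the lower-left corner."""

    n_rows: int
    n_cols: int
    origin_lon: float = 0.0
    origin_lat: float = 40.0
    cell_size: float = 0.05

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return lon, lat

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons, lats) 2-D arrays of cell-center coordinates, row 0 = north."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat + (self.n_rows - 1 - rows + 0.5) * self.cell_size
        lons, lats = np.meshgrid(lon, lat)
        return lons, lats

    def cell_polygon(self, row: int, col: int):
        """Shapely box of one cell's footprint."""
        x0 = self.origin_lon + col * self.cell_size
        y0 = self.origin_lat + (self.n_rows - 1 - row) * self.cell_size
        return shapely.box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


@dataclass
class RasterStack:
    """Named co-registered layers on one grid.

    ``scenario`` tags the climate snapshot the stack represents
    (``current`` or a glacial scenario such as ``lgm``).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    scenario: str = "current"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at_cells(self, cells: np.ndarray, layer_names: list[str] | None = None) -> np.ndarray:
        """Stack layer values at (row, col) index pairs into an (n, L) matrix."""
        names = layer_names or self.layer_names
        rows, cols = cells[:, 0], cells[:, 1]
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def finite_mask(self) -> np.ndarray:
        mask = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask


def write_ascii_grid(path: str | Path, data: np.ndarray, grid: GridSpec) -> None:
    """Write one layer as an ESRI ASCII grid; NaN cells become the nodata value."""
    out = np.where(np.isfinite(data), data, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon}\n"
        f"yllcorner {grid.origin_lat}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6f")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        n_rows=int(hdr["nrows"]),
        n_cols=int(hdr["ncols"]),
        origin_lon=hdr["xllcorner"],
        origin_lat=hdr["yllcorner"],
        cell_size=hdr["cellsize"],
    )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nodata = hdr.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match header {grid.shape}")
    return data, grid


def mask_to_polygon(mask: np.ndarray, grid: GridSpec):
    """Union of cell footprints where ``mask`` is True (a species range polygon)."""
    boxes = [grid.cell_polygon(r, c) for r, c in np.argwhere(mask)]
    if not boxes:
        return shapely.Polygon()
    return shapely.unary_union(boxes)


def write_geojson(path: str | Path, geoms: dict[str, object]) -> None:
    """Write named geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geoms.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path) -> dict[str, object]:
    with open(path) as fh:
        fc = json.load(fh)
    return {f["properties"].get("name", str(i)): shape(f["geometry"]) for i, f in enumerate(fc["features"])}
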