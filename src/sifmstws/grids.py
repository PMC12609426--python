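"""Geographic grids and raster containers.

All rasters live on a regular latitude/longitude grid (EPSG:4326), north-up,
cell-edge registered at the configured NW corner, with half-open cell
intervals: cell (i, j) spans ``[lat_max - (i+1)*cell, lat_max - i*cell)`` in
latitude and ``[lon_min + j*cell, lon_min + (j+1)*cell)`` in longitude.

Rasters are read and written as Esri ASCII grids (plain text, one file per
band); multi-band rasters get a small JSON sidecar listing the band files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "Raster", "read_raster", "write_raster"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic grid, north-up, NW-corner registered."""

    lat_max: float
    lon_min: float
    nrows: int
    ncols: int
    cell: float = 0.05

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @classmethod
    def from_bounds(
        cls, lat_min: float, lat_max: float, lon_min: float, lon_max: float, cell: float = 0.05
    ) -> "GridGeometry":
        nrows = (lat_max - lat_min) / cell
        ncols = (lon_max - lon_min) / cell
        if abs(nrows - round(nrows)) > 1e-8 or abs(ncols - round(ncols)) > 1e-8:
            raise ValueError(
                f"cell size {cell} does not divide extent "
                f"({lat_min}..{lat_max}, {lon_min}..{lon_max}) evenly"
            )
        return cls(lat_max=lat_max, lon_min=lon_min, nrows=round(nrows), ncols=round(ncols), cell=cell)

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.nrows * self.cell

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order)."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.cell

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell

    def cell_of(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Points outside the extent get index -1 in the offending axis.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((self.lat_max - lat) / self.cell).astype(int)
        col = np.floor((lon - self.lon_min) / self.cell).astype(int)
        row = np.where((row >= 0) & (row < self.nrows), row, -1)
        col = np.where((col >= 0) & (col < self.ncols), col, -1)
        return row, col

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat < self.lat_max) and (self.lon_min <= lon < self.lon_max)


@dataclass
class Raster:
    """Array plus grid geometry. ``values`` is (nrows, ncols) or (nbands, nrows, ncols)."""

    values: np.ndarray
    geom: GridGeometry
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D or 3-D (bands, rows, cols)")
        if v.shape[-2:] != (self.geom.nrows, self.geom.ncols):
            raise ValueError(
                f"values shape {v.shape} does not match geometry "
                f"({self.geom.nrows} x {self.geom.ncols})"
            )
        self.values = v

    @property
    def nbands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True where nodata), collapsed over bands."""
        v = self.values if self.values.ndim == 3 else self.values[None]
        if np.issubdtype(v.dtype, np.floating):
            m = np.isnan(v) | (v == self.nodata)
        else:
            m = v == self.nodata
        return m.any(axis=0)


def _write_ascii_band(path: Path, band: np.ndarray, geom: GridGeometry, nodata: float) -> None:
    band = np.asarray(band, dtype=float)
    band = np.where(np.isnan(band), nodata, band)
    header = (
        f"ncols {geom.ncols}\n"
        f"nrows {geom.nrows}\n"
        f"xllcorner {geom.lon_min!r}\n"
        f"yllcorner {geom.lat_min!r}\n"
        f"cellsize {geom.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, band, fmt="%.10g")


def _read_ascii_band(path: Path) -> tuple[np.ndarray, GridGeometry, float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(hdr["nrows"]), int(hdr["ncols"])
    cell = hdr["cellsize"]
    geom = GridGeometry(
        lat_max=hdr["yllcorner"] + nrows * cell, lon_min=hdr["xllcorner"],
        nrows=nrows, ncols=ncols, cell=cell,
    )
    nodata = hdr.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return values, geom, nodata


def write_raster(path: str | Path, raster: Raster) -> Path:
    """Write a raster as Esri ASCII text. Multi-band rasters are written as
    ``<stem>_b<i>.asc`` plus a ``<stem>.json`` sidecar naming the bands."""
    path = Path(path)
    if raster.values.ndim == 2:
        _write_ascii_band(path.with_suffix(".asc"), raster.values, raster.geom, raster.nodata)
        return path.with_suffix(".asc")
    path.parent.mkdir(parents=True, exist_ok=True)
    band_files = []
    for i in range(raster.nbands):
        bf = path.parent / f"{path.stem}_b{i + 1}.asc"
        _write_ascii_band(bf, raster.values[i], raster.geom, raster.nodata)
        band_files.append(bf.name)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"bands": band_files, "nodata": raster.nodata}, indent=1))
    return sidecar


def read_raster(path: str | Path, expect_geom: GridGeometry | None = None) -> Raster:
    """Read a raster written by :func:`write_raster`.

    Raises ``ValueError`` with both geometries printed if ``expect_geom`` is
    given and the stored grid does not match.
    """
    path = Path(path)
    if path.suffix == ".json":
        meta = json.loads(path.read_text())
        bands, geom, nodata = [], None, meta.get("nodata", -9999.0)
        for name in meta["bands"]:
            vals, g, _ = _read_ascii_band(path.parent / name)
            if geom is not None and g != geom:
                raise ValueError(f"band geometry mismatch: {g} vs {geom}")
            geom = g
            bands.append(vals)
        values = np.stack(bands)
    else:
        values, geom, nodata = _read_ascii_band(path)
    if expect_geom is not None and geom != expect_geom:
        raise ValueError(f"grid geometry mismatch: file has {geom}, expected {expect_geom}")
    return Raster(values=values, geom=geom, nodata=nodata)
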