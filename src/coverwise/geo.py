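"""Minimal north-up raster georeferencing and text-friendly raster/vector I/O.

Rasters are written as multiband TIFF (band-sequential pages, band order =
ascending wavelength) with a JSON sidecar carrying the geotransform,
wavelengths and nodata flag, or as ENVI BSQ with a plain-text header.
Vectors are written as GeoJSON.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine mapping between (row, col) and map coordinates.

    ``x0, y0`` are the map coordinates of the top-left corner of pixel
    (0, 0); ``gsd`` is the square pixel size in metres.
    """

    x0: float = 0.0
    y0: float = 0.0
    gsd: float = 1.0

    def pixel_center(self, row, col):
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.gsd
        y = self.y0 - (row + 0.5) * self.gsd
        return x, y

    def to_rowcol(self, x, y):
        """Row/col of the pixel containing map point (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.gsd).astype(int)
        row = np.floor((self.y0 - y) / self.gsd).astype(int)
        return row, col

    def to_gdal(self) -> tuple:
        return (self.x0, self.gsd, 0.0, self.y0, 0.0, -self.gsd)


def write_raster(path, data: np.ndarray, transform: GeoTransform,
                 wavelengths: Sequence[float] | None = None,
                 nodata_mask: np.ndarray | None = None) -> None:
    """Write a (B, R, C) or (R, C) array as TIFF + JSON sidecar."""
    import tifffile

    path = Path(path)
    arr = np.asarray(data)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "geotransform": transform.to_gdal(),
        "gsd": transform.gsd,
        "shape": list(arr.shape),
    }
    if wavelengths is not None:
        meta["wavelengths_nm"] = [float(w) for w in wavelengths]
    if nodata_mask is not None and bool(np.any(nodata_mask)):
        meta["nodata_rows_cols"] = np.argwhere(nodata_mask).tolist()
    path.with_suffix(path.suffix + ".aux.json").write_text(
        json.dumps(meta, indent=1))


def read_raster(path):
    """Read a raster written by :func:`write_raster`.

    Returns (array, GeoTransform, wavelengths-or-None).
    """
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".aux.json")
    transform = GeoTransform()
    wavelengths = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        g = meta["geotransform"]
        transform = GeoTransform(x0=g[0], y0=g[3], gsd=g[1])
        wavelengths = meta.get("wavelengths_nm")
    return arr, transform, wavelengths


def write_envi(path_base, data: np.ndarray, transform: GeoTransform,
               wavelengths: Sequence[float] | None = None) -> None:
    """Write a (B, R, C) cube as ENVI BSQ (.img) with a text header (.hdr)."""
    path_base = Path(path_base)
    arr = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if arr.ndim == 2:
        arr = arr[None]
    bands, rows, cols = arr.shape
    arr.tofile(path_base.with_suffix(".img"))
    lines = [
        "ENVI",
        "description = {coverwise synthetic cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        ("map info = {Arbitrary, 1, 1, "
         f"{transform.x0}, {transform.y0}, {transform.gsd}, {transform.gsd}}}"),
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.1f}" for w in wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = {" + wl + "}")
    path_base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


def polygons_to_geojson(polygons: Iterable, properties: Iterable[dict] | None = None) -> dict:
    """Shapely polygons -> GeoJSON FeatureCollection (mapping, not file)."""
    from shapely.geometry import mapping

    feats = []
    props = list(properties) if properties is not None else None
    for i, poly in enumerate(polygons):
        p = props[i] if props is not None else {}
        feats.append({"type": "Feature", "geometry": mapping(poly),
                      "properties": p})
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, collection: dict) -> None:
    Path(path).write_text(json.dumps(collection))
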