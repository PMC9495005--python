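"""Minimal georeferenced raster container with GeoTIFF I/O.

A raster is a stack of named float32 bands on a regular north-up grid in a
projected CRS (default EPSG:32722, UTM zone 22 S). Georeferencing follows the
GeoTIFF convention: the model tiepoint anchors the *outer corner* of the
top-left pixel, so pixel centers sit half a pixel inside the bounds.

Files are plain single-image GeoTIFFs written through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA); band names travel in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

NODATA = -9999.0
DEFAULT_EPSG = 32722  # UTM zone 22 S (WGS84), southern hemisphere

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclass
class Raster:
    """Multiband float32 raster on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (n_bands, n_rows, n_cols)
    band_names : list of str
    west, north : float
        Outer corner of the top-left pixel, map units (m).
    pixel_size : float
        Square pixel edge length in map units.
    crs_epsg : int
    nodata : float
    """

    data: np.ndarray
    band_names: list[str]
    west: float
    north: float
    pixel_size: float
    crs_epsg: int = DEFAULT_EPSG
    nodata: float = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")
        if len(self.band_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.data.shape[0]} bands"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds."""
        n_rows, n_cols = self.shape
        return (
            self.west,
            self.north - n_rows * self.pixel_size,
            self.west + n_cols * self.pixel_size,
            self.north,
        )

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D view; raises KeyError naming the band."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(
                f"band {name!r} not present (have {self.band_names})"
            ) from None
        return self.data[i]

    def mask_invalid(self) -> np.ndarray:
        """Boolean (rows, cols) array, True where ANY band is nodata/nonfinite."""
        bad = ~np.isfinite(self.data) | (self.data == self.nodata)
        return bad.any(axis=0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) 1-D arrays of column / row pixel-center coordinates."""
        n_rows, n_cols = self.shape
        x = self.west + (np.arange(n_cols) + 0.5) * self.pixel_size
        y = self.north - (np.arange(n_rows) + 0.5) * self.pixel_size
        return x, y

    def rowcol(self, easting, northing) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) of the containing pixel (floor rule)."""
        col = np.floor((np.asarray(easting, float) - self.west) / self.pixel_size)
        row = np.floor((self.north - np.asarray(northing, float)) / self.pixel_size)
        return row.astype(int), col.astype(int)


def _geokey_directory(epsg: int) -> tuple[int, ...]:
    # KeyDirectoryVersion, KeyRevision, MinorRevision, NumberOfKeys, then
    # (KeyID, TIFFTagLocation, Count, Value) quadruples.
    keys = [
        (1024, 0, 1, 1),      # GTModelTypeGeoKey = ModelTypeProjected
        (1025, 0, 1, 1),      # GTRasterTypeGeoKey = RasterPixelIsArea
        (3072, 0, 1, epsg),   # ProjectedCSTypeGeoKey
    ]
    out = [1, 1, 0, len(keys)]
    for k in keys:
        out.extend(k)
    return tuple(out)


def write_geotiff(raster: Raster, path) -> None:
    """Write a :class:`Raster` as a float32 GeoTIFF (planar bands)."""
    gkd = _geokey_directory(raster.crs_epsg)
    nodata_ascii = str(raster.nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (raster.pixel_size, raster.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, raster.west, raster.north, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(gkd), gkd),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii) + 1, nodata_ascii),
    ]
    description = json.dumps({"band_names": raster.band_names, "meta": raster.meta})
    if raster.n_bands == 1:
        data, planarconfig = raster.data[0], None
    else:
        data, planarconfig = raster.data, "separate"
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig=planarconfig,
        description=description,
        extratags=extratags,
    )


def read_geotiff(path) -> Raster:
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata = NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        epsg = DEFAULT_EPSG
        if _TAG_GEO_KEY_DIRECTORY in tags:
            gkd = tags[_TAG_GEO_KEY_DIRECTORY].value
            for i in range(4, len(gkd), 4):
                if gkd[i] == 3072:
                    epsg = int(gkd[i + 3])
        band_names = None
        meta: dict = {}
        desc = tags.get(270)
        if desc is not None:
            try:
                payload = json.loads(desc.value)
                band_names = payload.get("band_names")
                meta = payload.get("meta", {})
            except (json.JSONDecodeError, TypeError, AttributeError):
                pass
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if band_names is None:
        band_names = [f"band_{i + 1}" for i in range(data.shape[0])]
    # tiepoint maps raster (0,0) corner to model (X,Y)
    west, north = float(tiepoint[3]), float(tiepoint[4])
    return Raster(
        data=data,
        band_names=list(band_names),
        west=west,
        north=north,
        pixel_size=float(scale[0]),
        crs_epsg=epsg,
        nodata=nodata,
        meta=meta,
    )
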