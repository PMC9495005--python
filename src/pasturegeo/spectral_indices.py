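"""Dark-object subtraction and normalized-difference indices (NDVI, NDWI).

NDVI = (NIR - red) / (NIR + red) tracks green-vegetation vigor;
NDWI (Gao) = (NIR - SWIR1) / (NIR + SWIR1) tracks canopy water content.
Before band math, additive atmospheric path radiance is removed by
dark-object subtraction (DOS): per band, the darkest valid pixel (or a low
quantile of them) is taken as the haze offset and subtracted, clamping at
zero — the classic DOS1 image-based correction.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from ._raster import Raster

logger = logging.getLogger(__name__)

INDEX_BANDS = {
    "NDVI": ("nir", "red"),
    "NDWI": ("nir", "swir1"),
}

#: max value above which integer-scaled reflectance (x10000) is assumed
_INT_SCALE_THRESHOLD = 1.5


def _valid(raster: Raster, band: np.ndarray) -> np.ndarray:
    return np.isfinite(band) & (band != raster.nodata)


def normalize_reflectance(raster: Raster) -> Raster:
    """Return a raster with reflectance on the [0, 1] scale.

    Integer-scaled dialects (x10000, common in distributed level-2 products)
    are auto-detected by the band maximum and divided out with a log notice.
    """
    data = raster.data
    valid = np.isfinite(data) & (data != raster.nodata)
    if valid.any() and data[valid].max() > _INT_SCALE_THRESHOLD:
        logger.info("reflectance appears integer-scaled (max %.1f); dividing by 10000",
                    data[valid].max())
        scaled = np.where(valid, data / 10000.0, data)
        return replace(raster, data=scaled.astype(np.float32))
    return raster


def dos_correct(raster: Raster, percentile: float = 0.0) -> tuple[Raster, dict]:
    """Dark-object subtraction per band.

    The offset is the ``percentile`` quantile of each band's valid pixels
    (``percentile=0`` — the default — uses the band minimum); corrected
    values are max(band - offset, 0). Returns the corrected raster and a
    {band_name: offset} report.
    """
    if not 0.0 <= percentile <= 0.05:
        raise ValueError("percentile must be within [0, 0.05]")
    raster = normalize_reflectance(raster)
    corrected = raster.data.copy()
    offsets: dict[str, float] = {}
    for i, name in enumerate(raster.band_names):
        band = raster.data[i]
        valid = _valid(raster, band)
        if not valid.any():
            raise ValueError(f"band {name!r} has no valid pixels")
        offset = float(np.quantile(band[valid], percentile))
        offsets[name] = offset
        corrected[i][valid] = np.maximum(band[valid] - offset, 0.0)
    out = replace(raster, data=corrected,
                  meta={**raster.meta, "dos_offsets": offsets,
                        "dos_percentile": percentile})
    return out, offsets


def compute_index(raster: Raster, index_name: str) -> Raster:
    """Pixelwise normalized-difference index (NDVI or NDWI).

    Output values lie in [-1, 1] by construction for non-negative
    reflectances; pixels where either input band is nodata, or the band sum
    is zero, are nodata. Provenance (bands used, DOS offsets if present)
    rides in the output metadata.
    """
    if index_name not in INDEX_BANDS:
        raise ValueError(
            f"unknown index {index_name!r}; choose from {sorted(INDEX_BANDS)}"
        )
    plus_name, minus_name = INDEX_BANDS[index_name]
    a = raster.band(plus_name).astype(np.float64)
    b = raster.band(minus_name).astype(np.float64)
    valid = _valid(raster, a.astype(np.float32)) & _valid(raster, b.astype(np.float32))
    denom = a + b
    ok = valid & (denom != 0)
    out = np.full(a.shape, raster.nodata, dtype=np.float64)
    out[ok] = (a[ok] - b[ok]) / denom[ok]
    return Raster(
        data=out[None].astype(np.float32),
        band_names=[index_name],
        west=raster.west,
        north=raster.north,
        pixel_size=raster.pixel_size,
        crs_epsg=raster.crs_epsg,
        nodata=raster.nodata,
        meta={
            "index": index_name,
            "bands_used": [plus_name, minus_name],
            "dos_offsets": raster.meta.get("dos_offsets"),
        },
    )


def extract_at_points(index: Raster, points: pd.DataFrame,
                      points_crs_epsg: int | None = None,
                      column: str | None = None) -> pd.DataFrame:
    """Sample an index raster at point locations (nearest pixel center).

    Returns a frame of ``point_id`` and the sampled value; points outside
    the raster, or over nodata pixels, get NaN with a logged warning.
    Raises on CRS mismatch rather than silently transforming.
    """
    if points_crs_epsg is not None and points_crs_epsg != index.crs_epsg:
        raise ValueError(
            f"CRS mismatch: points EPSG:{points_crs_epsg} vs "
            f"raster EPSG:{index.crs_epsg}"
        )
    if column is None:
        column = index.band_names[0].lower()
    band = index.data[0]
    n_rows, n_cols = band.shape
    row, col = index.rowcol(points["easting"].to_numpy(),
                            points["northing"].to_numpy())
    inside = (row >= 0) & (row < n_rows) & (col >= 0) & (col < n_cols)
    vals = np.full(len(points), np.nan)
    r_in, c_in = row[inside], col[inside]
    sampled = band[r_in, c_in].astype(float)
    sampled[sampled == index.nodata] = np.nan
    vals[inside] = sampled
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d points fall outside the raster; reported missing", n_out)
    return pd.DataFrame({"point_id": points["point_id"].to_numpy(),
                         column: vals})
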