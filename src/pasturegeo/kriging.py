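"""Ordinary kriging on a regular grid from a fitted variogram model.

The predictor at a target x0 is the weighted mean z*(x0) = sum_i lambda_i
z(x_i) whose weights solve the ordinary-kriging system: pairwise model
semivariances bordered by the unbiasedness (sum-to-one) constraint enforced
through a Lagrange multiplier mu. The kriging variance is the minimized
error variance sum_i lambda_i gamma(x_i, x0) + mu.

A global neighborhood is used by default — every sample informs every
prediction, appropriate at the study's desk scale (196 points); a
``max_points`` option restricts to the nearest samples for larger inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.linalg import lu_factor, lu_solve
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from ._raster import DEFAULT_EPSG, NODATA, Raster, write_geotiff
from .variography import VariogramModel

logger = logging.getLogger(__name__)

_VARIANCE_FLOOR = -1e-10


@dataclass
class OKResult:
    """Single-target ordinary-kriging solution."""

    weights: np.ndarray
    lagrange: float
    estimate: float
    variance: float


@dataclass
class KrigingSurface:
    """Kriged prediction grid with per-cell kriging variances.

    ``predictions`` and ``variances`` are congruent (n_rows, n_cols) arrays;
    masked cells hold ``nodata``.
    """

    predictions: np.ndarray
    variances: np.ndarray
    west: float
    north: float
    pixel_size: float
    model: VariogramModel
    crs_epsg: int = DEFAULT_EPSG
    nodata: float = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.predictions.shape != self.variances.shape:
            raise ValueError("prediction and variance grids must be congruent")

    def to_raster(self) -> Raster:
        return Raster(
            data=np.stack([self.predictions, self.variances]),
            band_names=["prediction", "kriging_variance"],
            west=self.west,
            north=self.north,
            pixel_size=self.pixel_size,
            crs_epsg=self.crs_epsg,
            nodata=self.nodata,
            meta={**self.meta, "model": self.model.to_dict()},
        )


def _check_samples(xy: np.ndarray) -> None:
    if len(xy) < 2:
        raise ValueError("ordinary kriging needs at least 2 sample locations")
    _, inverse, counts = np.unique(
        xy.round(decimals=6), axis=0, return_inverse=True, return_counts=True
    )
    if counts.max() > 1:
        dupes = np.nonzero(counts[inverse] > 1)[0]
        raise ValueError(
            f"duplicate sample locations at row indices {dupes.tolist()}; "
            "deduplicate or jitter before kriging"
        )


def _ok_matrix(xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    A = np.empty((n + 1, n + 1))
    gamma = model.semivariance(d.ravel()).reshape(n, n)
    np.fill_diagonal(gamma, 0.0)
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def _rhs(xy: np.ndarray, targets: np.ndarray, model: VariogramModel) -> np.ndarray:
    d = np.linalg.norm(xy[:, None, :] - targets[None, :, :], axis=-1)
    b = np.empty((len(xy) + 1, len(targets)))
    gamma = model.semivariance(d.ravel()).reshape(d.shape)
    # target support is distinct from the sample's: a target coinciding with
    # a sample sees the nugget limit gamma(0+) = C0, so the predictor
    # smooths noisy data rather than honoring it exactly when C0 > 0
    gamma[d == 0] = model.nugget
    b[:-1] = gamma
    b[-1] = 1.0
    return b


def solve_ok_weights(xy: np.ndarray, values: np.ndarray, target,
                     model: VariogramModel) -> OKResult:
    """Solve the ordinary-kriging system for one target location.

    Returns the weights (summing to one), the Lagrange multiplier, the
    prediction, and the kriging variance (clipped at zero if a tiny negative
    value arises numerically).
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_samples(xy)
    A = _ok_matrix(xy, model)
    b = _rhs(xy, np.asarray(target, float)[None, :], model)[:, 0]
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular ordinary-kriging system: {exc}")
    lam, mu = sol[:-1], sol[-1]
    variance = float(lam @ b[:-1] + mu)
    if variance < _VARIANCE_FLOOR:
        logger.warning("kriging variance %.3e below numerical floor; clipping",
                       variance)
    variance = max(variance, 0.0)
    return OKResult(
        weights=lam,
        lagrange=float(mu),
        estimate=float(lam @ values),
        variance=variance,
    )


def krige_points(xy: np.ndarray, values: np.ndarray, targets: np.ndarray,
                 model: VariogramModel) -> tuple[np.ndarray, np.ndarray]:
    """Predict at many targets with one matrix factorization.

    Returns (estimates, variances), both length len(targets).
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    _check_samples(xy)
    A = _ok_matrix(xy, model)
    B = _rhs(xy, targets, model)
    try:
        lu = lu_factor(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular ordinary-kriging system: {exc}")
    sol = lu_solve(lu, B)
    lam, mu = sol[:-1], sol[-1]
    est = values @ lam
    var = np.einsum("ij,ij->j", lam, B[:-1]) + mu
    n_clip = int((var < _VARIANCE_FLOOR).sum())
    if n_clip:
        logger.warning("%d kriging variances below numerical floor; clipping",
                       n_clip)
    return est, np.maximum(var, 0.0)


def krige_grid(samples: pd.DataFrame, variable: str, model: VariogramModel,
               pixel_size: float = 1.0,
               mask: BaseGeometry | list | None = None,
               bounds: tuple[float, float, float, float] | None = None,
               max_points: int | None = None) -> KrigingSurface:
    """Ordinary kriging of ``variable`` onto a regular grid.

    Parameters
    ----------
    samples : DataFrame with ``easting``, ``northing``, and ``variable``;
        rows with missing values are dropped.
    pixel_size : grid resolution in meters (default 1 m — finer than the
        10 m sampling mesh).
    mask : shapely geometry (or list of geometries) delimiting the paddocks;
        cells whose centers fall outside are nodata. Default: the samples'
        bounding box (no masking).
    bounds : (west, south, east, north); default the mask's (or samples')
        bounds.
    max_points : if given, each cell uses only its ``max_points`` nearest
        samples instead of the global neighborhood.
    """
    df = samples.dropna(subset=[variable])
    if df.empty:
        raise ValueError(f"no samples with non-missing {variable!r}")
    xy = df[["easting", "northing"]].to_numpy(dtype=float)
    values = df[variable].to_numpy(dtype=float)

    if isinstance(mask, (list, tuple)):
        mask = unary_union(list(mask))
    if bounds is None:
        if mask is not None:
            bounds = mask.bounds
        else:
            bounds = (xy[:, 0].min(), xy[:, 1].min(),
                      xy[:, 0].max(), xy[:, 1].max())
    west, south, east, north = map(float, bounds)
    n_cols = max(int(np.ceil((east - west) / pixel_size)), 1)
    n_rows = max(int(np.ceil((north - south) / pixel_size)), 1)

    x = west + (np.arange(n_cols) + 0.5) * pixel_size
    y = north - (np.arange(n_rows) + 0.5) * pixel_size
    gx, gy = np.meshgrid(x, y)
    flat_xy = np.column_stack([gx.ravel(), gy.ravel()])

    if mask is not None:
        inside = shapely.contains_xy(mask, flat_xy[:, 0], flat_xy[:, 1])
    else:
        inside = np.ones(len(flat_xy), dtype=bool)

    pred = np.full(len(flat_xy), NODATA)
    var = np.full(len(flat_xy), NODATA)
    targets = flat_xy[inside]
    if len(targets):
        if max_points is not None and max_points < len(xy):
            est = np.empty(len(targets))
            kv = np.empty(len(targets))
            for i, t in enumerate(targets):
                order = np.argsort(np.linalg.norm(xy - t, axis=1))[:max_points]
                r = solve_ok_weights(xy[order], values[order], t, model)
                est[i], kv[i] = r.estimate, r.variance
        else:
            est, kv = krige_points(xy, values, targets, model)
        pred[inside] = est
        var[inside] = kv

    return KrigingSurface(
        predictions=pred.reshape(n_rows, n_cols),
        variances=var.reshape(n_rows, n_cols),
        west=west,
        north=north,
        pixel_size=float(pixel_size),
        model=model,
        meta={"variable": variable, "n_samples": int(len(xy))},
    )


def leave_one_out(samples: pd.DataFrame, variable: str,
                  model: VariogramModel) -> pd.DataFrame:
    """Leave-one-out cross-validation: re-krige each sample from the others.

    Returns a frame with observed, predicted, kriging variance, and residual
    per held-out point.
    """
    df = samples.dropna(subset=[variable]).reset_index(drop=True)
    xy = df[["easting", "northing"]].to_numpy(dtype=float)
    values = df[variable].to_numpy(dtype=float)
    _check_samples(xy)
    rows = []
    for i in range(len(df)):
        keep = np.arange(len(df)) != i
        r = solve_ok_weights(xy[keep], values[keep], xy[i], model)
        rows.append((values[i], r.estimate, r.variance, values[i] - r.estimate))
    return pd.DataFrame(
        rows, columns=["observed", "predicted", "kriging_variance", "residual"]
    )


def export_surface(surface: KrigingSurface, path) -> None:
    """Write prediction + variance bands as a float32 GeoTIFF."""
    write_geotiff(surface.to_raster(), path)
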