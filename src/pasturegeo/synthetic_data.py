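"""Synthetic stand-ins for the field campaign: sampling design, Gaussian
random fields, and co-varying multispectral scenes.

The study system is a 17,150 m² rotational grazing pasture split into seven
2450 m² paddocks, sampled on a regular ~10 m mesh of 28 points per paddock
(196 points total) for soil pH at three depths and forage dry/green matter.
The raw field measurements are unpublished, so this module generates
statistically faithful substitutes:

* :func:`build_sampling_design` — the deterministic paddock grid geometry;
* :func:`simulate_field` — stationary Gaussian random fields whose variogram
  is prescribed (so published semivariogram parameters can serve as the
  generating truth for recovery experiments);
* :func:`synthesize_scene` — red/NIR/SWIR1 reflectance rasters whose
  noise-free NDVI is an affine function of the dry-matter field, with
  additive per-band path radiance that dark-object subtraction can remove.

All randomness flows from a single integer seed per spec; identical specs
give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from shapely.geometry import box

from ._raster import DEFAULT_EPSG, NODATA, Raster
from .variography import VariogramModel

CSV_COLUMNS = [
    "point_id", "easting", "northing", "paddock",
    "ph_0_20", "ph_20_30", "ph_30_40", "dm", "gm",
]

#: Origin of the default layout, near the published site coordinates
#: (UTM zone 22 S).
DEFAULT_ORIGIN = (623_600.0, 9_311_900.0)


def substream_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from a global seed."""
    return (int(seed) ^ zlib.crc32(label.encode())) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

@dataclass
class PaddockLayout:
    """Geometry of the paddock strip and its sampling mesh.

    Defaults reproduce the study design: seven 2450 m² rectangles
    (35 m easting x 70 m northing) laid side-by-side along the easting axis,
    fence margins of 2.5 m excluded at the 70 m ends and side margins of 5 m
    at the 35 m sides, a 10 m mesh along the long axis, and 28 points per
    paddock. The 25 m-wide interior cannot hold four columns at an exact
    10 m spacing, so the target per-paddock count is met by spacing the
    cross-axis columns evenly (25/3 m); per-axis spacings are recorded in
    the emitted table's ``attrs``.
    """

    n_paddocks: int = 7
    paddock_width_m: float = 35.0    # easting extent of one paddock
    paddock_length_m: float = 70.0   # northing extent
    fence_margin_m: float = 2.5      # excluded at the northing ends
    side_margin_m: float = 5.0       # excluded at the easting sides
    grid_spacing_m: float = 10.0
    origin_easting: float = DEFAULT_ORIGIN[0]
    origin_northing: float = DEFAULT_ORIGIN[1]
    points_per_paddock_target: int = 28

    def __post_init__(self) -> None:
        if self.n_paddocks < 1:
            raise ValueError("n_paddocks must be >= 1")
        for name in ("paddock_width_m", "paddock_length_m", "grid_spacing_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fence_margin_m < 0 or self.side_margin_m < 0:
            raise ValueError("margins must be non-negative")

    @property
    def paddock_area_m2(self) -> float:
        return self.paddock_width_m * self.paddock_length_m

    @property
    def total_area_m2(self) -> float:
        return self.n_paddocks * self.paddock_area_m2

    def paddock_polygons(self) -> list:
        """Shapely boxes, one per paddock, ordered west to east."""
        polys = []
        for k in range(self.n_paddocks):
            x0 = self.origin_easting + k * self.paddock_width_m
            polys.append(box(x0, self.origin_northing,
                             x0 + self.paddock_width_m,
                             self.origin_northing + self.paddock_length_m))
        return polys


def build_sampling_design(layout: PaddockLayout | None = None) -> pd.DataFrame:
    """Deterministic regular sampling mesh over the paddock strip.

    Returns a table with columns ``point_id, easting, northing, paddock``
    (one row per sample location). Within each paddock the interior (after
    margins) carries ``grid_spacing_m``-spaced rows along the long (northing)
    axis, centered, and as many evenly spaced columns across the short axis
    as the per-paddock target requires.

    Raises
    ------
    ValueError
        If the margins leave no interior, or if the per-paddock target is not
        a multiple of the number of long-axis rows (the error names the
        nearest feasible counts).
    """
    if layout is None:
        layout = PaddockLayout()

    interior_w = layout.paddock_width_m - 2 * layout.side_margin_m
    interior_l = layout.paddock_length_m - 2 * layout.fence_margin_m
    if interior_w <= 0 or interior_l <= 0:
        raise ValueError(
            "margins leave no paddock interior: "
            f"interior is {interior_w:.2f} m x {interior_l:.2f} m"
        )

    s = layout.grid_spacing_m
    n_long = int(np.floor(interior_l / s)) + 1
    target = layout.points_per_paddock_target
    if target % n_long != 0:
        feasible = (n_long * (target // n_long), n_long * (target // n_long + 1))
        raise ValueError(
            f"target of {target} points per paddock is infeasible with "
            f"{n_long} rows at {s} m spacing; nearest feasible counts are "
            f"{feasible[0]} or {feasible[1]}"
        )
    n_cross = target // n_long

    # rows: exact grid spacing, centered within the interior
    row_span = (n_long - 1) * s
    row_start = layout.fence_margin_m + (interior_l - row_span) / 2.0
    rel_north = row_start + s * np.arange(n_long)
    # columns: evenly spaced across the interior (endpoints included)
    if n_cross == 1:
        rel_east = np.array([layout.side_margin_m + interior_w / 2.0])
    else:
        rel_east = layout.side_margin_m + np.linspace(0.0, interior_w, n_cross)

    records = []
    for k in range(layout.n_paddocks):
        x0 = layout.origin_easting + k * layout.paddock_width_m
        for e in rel_east:
            for n in rel_north:
                records.append((x0 + e, layout.origin_northing + n, k + 1))
    df = pd.DataFrame(records, columns=["easting", "northing", "paddock"])
    df.insert(0, "point_id", [f"P{p:02d}-{i:03d}" for i, p in
                              zip(range(1, len(df) + 1), df["paddock"])])
    df.attrs["spacing_long_axis_m"] = s
    df.attrs["spacing_cross_axis_m"] = (
        interior_w / (n_cross - 1) if n_cross > 1 else float("nan")
    )
    df.attrs["crs_epsg"] = DEFAULT_EPSG
    return df


def write_points_csv(points: pd.DataFrame, path) -> None:
    """Write the canonical point-table CSV (missing values empty)."""
    out = points.reindex(columns=CSV_COLUMNS)
    out.to_csv(path, index=False, na_rep="")


def read_points_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"point CSV missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Generating truth for one simulated variable: a variogram model, a
    stationary mean, and a seed."""

    variogram: VariogramModel
    mean: float
    seed: int


def _simulation_model(model: VariogramModel, max_dist: float) -> VariogramModel:
    """Bounded surrogate for simulation.

    The linear variogram has no finite-variance stationary representation, so
    it is replaced by a spherical model whose near-origin slope matches the
    linear slope C1/a inside the sampled extent: range = 1.5 * max_dist,
    partial sill = (C1/a) * max_dist. Bounded families pass through
    unchanged.
    """
    if model.family != "linear":
        return model
    slope = model.partial_sill / model.range_m
    surrogate = VariogramModel(
        family="spherical",
        nugget=model.nugget,
        partial_sill=slope * max_dist,
        range_m=1.5 * max_dist,
        variable=model.variable,
    )
    surrogate.meta["surrogate_for"] = "linear"
    return surrogate


def simulate_field(points: pd.DataFrame, spec: FieldSpec,
                   jitter: float = 1e-10) -> np.ndarray:
    """Draw one realization of a stationary Gaussian random field at the
    sample locations.

    The covariance is C(h) = C1 * (1 - gamma_normalized(h)) from the spec's
    variogram, plus independent nugget noise of variance C0 at each point.
    Dense Cholesky factorization (suitable up to a few thousand points); a
    small diagonal jitter guards against numerically indefinite matrices.
    Same spec (including seed) -> bit-identical vector.
    """
    xy = points[["easting", "northing"]].to_numpy(dtype=float)
    n = len(xy)
    if n > 5000:
        raise ValueError("dense simulation limited to <= 5000 points")

    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    model = _simulation_model(spec.variogram, float(d.max()) if n > 1 else 1.0)
    c0, c1 = model.nugget, model.partial_sill

    rng = np.random.default_rng(spec.seed)
    if c1 == 0.0:
        correlated = np.zeros(n)
    else:
        # gamma(h) - C0 == C1 * gamma_normalized(h) for h > 0
        gamma = model.semivariance(d.ravel()).reshape(n, n)
        np.fill_diagonal(gamma, 0.0)
        cov = c1 - np.where(d > 0, gamma - c0, 0.0)
        cov[d == 0] = c1
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance not positive semi-definite for variogram "
                f"{model.family}(C0={c0}, C1={c1}, a={model.range_m})"
            ) from exc
        correlated = chol @ rng.standard_normal(n)
    nugget_noise = (
        np.sqrt(c0) * rng.standard_normal(n) if c0 > 0 else np.zeros(n)
    )
    return spec.mean + correlated + nugget_noise


# ---------------------------------------------------------------------------
# multispectral scene synthesis
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Recipe for a synthetic red/NIR/SWIR1 scene tied to the DM field.

    ``biomass_link`` maps dry matter (ton/ha) to noise-free NDVI before any
    band synthesis: NDVI = slope*DM + intercept + N(0, noise_sd²).
    ``path_radiance`` offsets (reflectance units) are added per band last, so
    dark-object subtraction can recover the clean bands.
    """

    pixel_size_m: float = 10.0
    biomass_link: dict = field(
        default_factory=lambda: {"slope": 0.04, "intercept": 0.35, "noise_sd": 0.10}
    )
    path_radiance: dict = field(
        default_factory=lambda: {"red": 0.03, "nir": 0.02, "swir1": 0.01}
    )
    brightness: float = 0.6   # NIR + red total reflectance, fixed
    ndwi_fraction: float = 0.5  # noise-free NDWI = fraction * NDVI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")


def synthesize_scene(points: pd.DataFrame, spec: SceneSpec,
                     layout: PaddockLayout | None = None) -> Raster:
    """Build a co-registered multiband reflectance raster from the DM field.

    Dry matter is interpolated to pixel centers (piecewise-linear inside the
    sample hull, nearest-neighbour outside), mapped to NDVI through the
    biomass link, and decomposed into red/NIR bands of fixed total
    brightness so the pixelwise NDVI of the noise-free scene reproduces the
    link exactly. SWIR1 is derived the same way from a proportional NDWI.
    Per-band path-radiance offsets are added last.
    """
    if layout is None:
        layout = PaddockLayout()
    if points["dm"].isna().any():
        raise ValueError("dm must be present at all points to synthesize a scene")
    if (spec.pixel_size_m > layout.paddock_width_m
            or spec.pixel_size_m > layout.paddock_length_m):
        raise ValueError(
            f"pixel size {spec.pixel_size_m} m exceeds a paddock dimension"
        )

    pad = spec.pixel_size_m  # one-pixel rim beyond the paddock strip
    west = layout.origin_easting - pad
    north = layout.origin_northing + layout.paddock_length_m + pad
    east = layout.origin_easting + layout.n_paddocks * layout.paddock_width_m + pad
    south = layout.origin_northing - pad
    n_cols = int(np.ceil((east - west) / spec.pixel_size_m))
    n_rows = int(np.ceil((north - south) / spec.pixel_size_m))

    x = west + (np.arange(n_cols) + 0.5) * spec.pixel_size_m
    y = north - (np.arange(n_rows) + 0.5) * spec.pixel_size_m
    gx, gy = np.meshgrid(x, y)

    xy = points[["easting", "northing"]].to_numpy(dtype=float)
    dm = points["dm"].to_numpy(dtype=float)
    dm_grid = griddata(xy, dm, (gx, gy), method="linear")
    nearest = griddata(xy, dm, (gx, gy), method="nearest")
    dm_grid = np.where(np.isnan(dm_grid), nearest, dm_grid)

    link = spec.biomass_link
    ndvi = link["slope"] * dm_grid + link["intercept"]
    if link.get("noise_sd", 0.0) > 0:
        rng = np.random.default_rng(spec.seed)
        ndvi = ndvi + rng.normal(0.0, link["noise_sd"], size=ndvi.shape)
    # keep reflectances strictly positive after decomposition
    ndvi = np.clip(ndvi, -0.99, 0.99)

    s = spec.brightness
    nir = s * (1.0 + ndvi) / 2.0
    red = s * (1.0 - ndvi) / 2.0
    ndwi = np.clip(spec.ndwi_fraction * ndvi, -0.99, 0.99)
    # solve (nir - swir)/(nir + swir) = ndwi for swir
    swir1 = nir * (1.0 - ndwi) / (1.0 + ndwi)

    bands = np.stack([red, nir, swir1])
    # plant a zero-reflectance dark object in the rim (south-west corner,
    # outside the paddocks) so image-based DOS is well-posed: after the
    # additive offsets, each band's minimum IS its path radiance
    bands[:, -1, 0] = 0.0
    if bands.max() > 1.2:
        raise ValueError("synthesized reflectance exceeds 1.2 before offsets")
    offsets = np.array([spec.path_radiance.get(b, 0.0)
                        for b in ("red", "nir", "swir1")])
    bands = bands + offsets[:, None, None]

    return Raster(
        data=bands.astype(np.float32),
        band_names=["red", "nir", "swir1"],
        west=west,
        north=north,
        pixel_size=spec.pixel_size_m,
        crs_epsg=DEFAULT_EPSG,
        nodata=NODATA,
        meta={
            "path_radiance": {k: float(v) for k, v in spec.path_radiance.items()},
            "biomass_link": {k: float(v) for k, v in spec.biomass_link.items()},
            "seed": int(spec.seed),
        },
    )
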