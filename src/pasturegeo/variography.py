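"""Empirical semivariograms, variogram-model fitting, and spatial-dependence
classification.

The empirical semivariogram is the classical Matheron moment estimator

    gamma_hat(h) = 1 / (2 N(h)) * sum_i [Z(x_i) - Z(x_i + h)]^2

computed over unordered point pairs grouped into distance bins. Four isotropic
model families are supported — spherical, exponential, Gaussian, and linear —
parameterised by nugget C0, partial sill C1, and range ``a``. Models are
fitted to the binned estimator by weighted least squares (weights = pair
counts), ranked by coefficient of determination and residual sum of squares,
and summarised by the degree of spatial dependence (DSD), the
nugget-to-sill percentage 100*C0/(C0+C1) with the Cambardella class bounds
(strong < 25%, moderate 25–75%, weak > 75%).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian", "linear")

#: Tie-break preference when R²/RSS do not separate candidate fits
#: (parsimony ordering: bounded, simplest shapes first).
_FAMILY_PREFERENCE = {f: i for i, f in enumerate(FAMILIES)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalVariogram:
    """Binned empirical semivariogram.

    ``lag_centers`` are the mean pairwise distances within each occupied bin
    (strictly increasing); ``semivariances`` the Matheron estimates; and
    ``pair_counts`` the number of unordered pairs per bin. Empty bins are
    dropped rather than reported as zeros.
    """

    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    n_bins: int
    sample_variance: float = float("nan")

    def __post_init__(self) -> None:
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (len(self.lag_centers) == len(self.semivariances) == len(self.pair_counts)):
            raise ValueError("bin arrays must have equal length")
        if np.any(self.semivariances < 0):
            raise ValueError("semivariance cannot be negative")
        if np.any(self.pair_counts < 1):
            raise ValueError("reported bins must contain at least one pair")
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValueError("lag centers must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_center": self.lag_centers,
                "semivariance": self.semivariances,
                "pair_count": self.pair_counts,
            }
        )


@dataclass
class VariogramModel:
    """Fitted (or prescribed) isotropic variogram model.

    ``range_m`` is the model range ``a``; ``practical_range_m`` is the
    distance at which the curve reaches ~95% of its sill (equal to ``a`` for
    the spherical model, ``3a`` exponential, ``sqrt(3)a`` Gaussian; for the
    unbounded linear model both the "sill" and the practical range are
    reported at the fit's maximum lag and flagged via ``sill_at_max_lag``).
    """

    family: str
    nugget: float
    partial_sill: float
    range_m: float
    r_squared: float = float("nan")
    rss: float = float("nan")
    n_bins: int = 0
    max_lag_m: float = float("nan")
    variable: str | None = None
    sill_at_max_lag: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.range_m <= 0:
            raise ValueError("range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def practical_range_m(self) -> float:
        return practical_range(self.family, self.range_m)

    @property
    def dsd_percent(self) -> float:
        return classify_dsd(self.nugget, self.partial_sill)[0]

    @property
    def dsd_class(self) -> str:
        return classify_dsd(self.nugget, self.partial_sill)[1]

    def semivariance(self, h) -> np.ndarray:
        return model_semivariance(
            self.family, self.nugget, self.partial_sill, self.range_m, h
        )

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) implied by the model.

        Only meaningful for bounded families; for ``linear`` this is the
        covariance of the spherical surrogate used in simulation.
        """
        h = np.asarray(h, dtype=float)
        return self.sill - self.semivariance(h)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "sill": self.sill,
            "range_m": self.range_m,
            "practical_range_m": self.practical_range_m,
            "r_squared": self.r_squared,
            "rss": self.rss,
            "dsd_percent": self.dsd_percent,
            "dsd_class": self.dsd_class,
            "n_bins": self.n_bins,
            "max_lag_m": self.max_lag_m,
            "sill_at_max_lag": self.sill_at_max_lag,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(
            family=d["family"],
            nugget=d["nugget"],
            partial_sill=d.get("partial_sill", d["sill"] - d["nugget"]),
            range_m=d["range_m"],
            r_squared=d.get("r_squared", float("nan")),
            rss=d.get("rss", float("nan")),
            n_bins=d.get("n_bins", 0),
            max_lag_m=d.get("max_lag_m", float("nan")),
            variable=d.get("variable"),
            sill_at_max_lag=d.get("sill_at_max_lag", False),
        )

    @classmethod
    def from_json(cls, path) -> "VariogramModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def model_semivariance(family: str, nugget: float, partial_sill: float,
                       range_m: float, h) -> np.ndarray | float:
    """Evaluate a variogram model at lag(s) ``h`` (meters).

    By convention gamma(0) = 0 exactly; the nugget appears as the limit from
    above (gamma(0+) -> C0). Scalar in, scalar out.

    Families
    --------
    spherical : C0 + C1*(1.5 u - 0.5 u^3) for u = h/a < 1, else C0 + C1
    exponential : C0 + C1*(1 - exp(-h/a))
    gaussian : C0 + C1*(1 - exp(-(h/a)^2))
    linear : C0 + (C1/a)*h  (unbounded; C1/a is the slope)
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if nugget < 0 or partial_sill < 0 or range_m <= 0:
        raise ValueError("require nugget >= 0, partial_sill >= 0, range > 0")
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("lag distance h must be non-negative")
    scalar = h_arr.ndim == 0
    h_arr = np.atleast_1d(h_arr)

    u = h_arr / range_m
    if family == "spherical":
        gamma = nugget + partial_sill * np.where(
            u < 1.0, 1.5 * u - 0.5 * u ** 3, 1.0
        )
    elif family == "exponential":
        gamma = nugget + partial_sill * (1.0 - np.exp(-u))
    elif family == "gaussian":
        gamma = nugget + partial_sill * (1.0 - np.exp(-(u ** 2)))
    else:  # linear
        gamma = nugget + (partial_sill / range_m) * h_arr

    gamma = np.where(h_arr == 0.0, 0.0, gamma)
    return float(gamma[0]) if scalar else gamma


def practical_range(family: str, range_m: float) -> float:
    """Distance at which the model reaches ~95% of its sill.

    spherical -> a (exact sill); exponential -> 3a; gaussian -> sqrt(3)*a;
    linear -> a by convention (no sill exists).
    """
    if range_m <= 0:
        raise ValueError("range must be positive")
    if family == "exponential":
        return 3.0 * range_m
    if family == "gaussian":
        return math.sqrt(3.0) * range_m
    if family in ("spherical", "linear"):
        return range_m
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def classify_dsd(nugget: float, partial_sill: float) -> tuple[float, str]:
    """Degree of spatial dependence: 100*C0/(C0+C1) and its Cambardella class.

    strong if < 25%, weak if > 75%, moderate otherwise (bounds closed on the
    moderate side: 25% and 75% are both moderate).
    """
    if nugget < 0 or partial_sill < 0:
        raise ValueError("nugget and partial sill must be non-negative")
    sill = nugget + partial_sill
    if sill == 0:
        raise ValueError("sill C0 + C1 is zero; DSD undefined")
    pct = 100.0 * nugget / sill
    if pct < 25.0:
        cls = "strong"
    elif pct > 75.0:
        cls = "weak"
    else:
        cls = "moderate"
    return pct, cls


# ---------------------------------------------------------------------------
# empirical estimator
# ---------------------------------------------------------------------------

def empirical_semivariogram(points: pd.DataFrame, variable: str,
                            n_bins: int = 12,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Matheron estimator of the semivariogram from a sample-point table.

    Parameters
    ----------
    points : DataFrame with ``easting``, ``northing`` and ``variable`` columns.
        Rows with a missing value of ``variable`` are dropped.
    n_bins : number of equal-width distance bins (>= 3).
    max_lag : largest lag considered; default half the maximum pairwise
        distance (standard variography practice — estimates beyond that are
        supported by too few, highly overlapping pairs).

    Every unordered pair at distance <= max_lag contributes once; bins with
    no pairs are omitted. Reported lag centers are the mean pair distance
    within each bin.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    df = points.dropna(subset=[variable])
    if len(df) < 2:
        raise ValueError(
            f"need at least 2 points with non-missing {variable!r}, have {len(df)}"
        )
    if len(df) < 10:
        logger.warning(
            "only %d points with non-missing %r; semivariogram estimates "
            "will be unstable", len(df), variable)
    xy = df[["easting", "northing"]].to_numpy(dtype=float)
    z = df[variable].to_numpy(dtype=float)

    dists = pdist(xy)
    if np.all(dists == 0):
        raise ValueError("all points are coincident; no spatial structure to estimate")
    sq_diffs = pdist(z[:, None], metric="sqeuclidean")

    d_max = float(dists.max())
    if max_lag is None:
        max_lag = d_max / 2.0
    if max_lag > d_max:
        raise ValueError(
            f"max_lag {max_lag} exceeds the maximum pairwise distance {d_max:.3f}"
        )

    edges = np.linspace(0.0, max_lag, n_bins + 1)
    keep = (dists > 0) & (dists <= max_lag)
    d, s = dists[keep], sq_diffs[keep]
    # right-closed bins; distance exactly 0 excluded (duplicate locations)
    idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=s, minlength=n_bins)
    dist_sums = np.bincount(idx, weights=d, minlength=n_bins)
    occupied = counts > 0

    gamma = sums[occupied] / (2.0 * counts[occupied])
    centers = dist_sums[occupied] / counts[occupied]

    return EmpiricalVariogram(
        lag_centers=centers,
        semivariances=gamma,
        pair_counts=counts[occupied],
        max_lag=float(max_lag),
        n_bins=n_bins,
        sample_variance=float(np.var(z, ddof=1)),
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _initial_guess(emp: EmpiricalVariogram) -> tuple[float, float, float]:
    """Data-driven start: nugget from the first bin, sill from the sample
    variance, range from where the estimator first reaches 95% of it."""
    sill0 = emp.sample_variance
    if not np.isfinite(sill0) or sill0 <= 0:
        sill0 = float(np.mean(emp.semivariances)) or 1.0
    c0 = min(float(emp.semivariances[0]), sill0)
    c1 = max(sill0 - c0, 1e-12 * sill0 + 1e-30)
    reached = np.nonzero(emp.semivariances >= 0.95 * sill0)[0]
    a0 = float(emp.lag_centers[reached[0]]) if len(reached) else float(emp.max_lag)
    a0 = max(a0, float(emp.lag_centers[0]))
    return c0, c1, a0


def _fit_one_family(family: str, emp: EmpiricalVariogram,
                    weights: np.ndarray) -> VariogramModel:
    h = emp.lag_centers
    g = emp.semivariances
    w = np.sqrt(weights)

    if family == "linear":
        # weighted linear regression gamma = C0 + b*h, closed form
        W = weights
        A = np.column_stack([np.ones_like(h), h])
        coef, *_ = np.linalg.lstsq(A * np.sqrt(W)[:, None], g * np.sqrt(W), rcond=None)
        c0, slope = coef
        c0 = max(c0, 0.0)
        slope = max(slope, 0.0)
        a = float(emp.max_lag)
        params = (c0, slope * a, a)
    else:
        c0_0, c1_0, a_0 = _initial_guess(emp)
        a_hi = 2.0 * emp.max_lag

        def residuals(p):
            c0, c1, a = p
            return w * (model_semivariance(family, c0, c1, a, h) - g)

        res = optimize.least_squares(
            residuals,
            x0=[c0_0, c1_0, min(max(a_0, 1e-6), a_hi)],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, a_hi]),
            method="trf",
        )
        if not res.success:
            raise RuntimeError(f"{family} fit failed: {res.message}")
        params = tuple(res.x)

    c0, c1, a = params
    pred = model_semivariance(family, c0, max(c1, 0.0), a, h)
    rss = float(np.sum((g - pred) ** 2))
    sst = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss < 1e-30 else 0.0)
    return VariogramModel(
        family=family,
        nugget=float(c0),
        partial_sill=float(max(c1, 0.0)),
        range_m=float(a),
        r_squared=r2,
        rss=rss,
        n_bins=len(h),
        max_lag_m=float(emp.max_lag),
        sill_at_max_lag=(family == "linear"),
    )


def fit_variogram(emp: EmpiricalVariogram,
                  families: tuple[str, ...] = FAMILIES,
                  weighting: str = "pair_count") -> list[VariogramModel]:
    """Fit candidate model families to a binned semivariogram; return them
    ranked best-first.

    Weighted least squares with weights equal to per-bin pair counts
    (``weighting="cressie"`` uses N(h)/gamma_model(h)^2 reweighting instead).
    Ranking is lexicographic: highest R², then lowest RSS, then the parsimony
    order spherical > exponential > gaussian > linear. Families whose
    optimiser fails are dropped with a warning; if all fail an error is
    raised.
    """
    if len(emp.lag_centers) < 4:
        raise ValueError("need at least 4 occupied bins to fit a variogram model")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    if weighting not in ("pair_count", "cressie"):
        raise ValueError("weighting must be 'pair_count' or 'cressie'")

    base_w = emp.pair_counts.astype(float)
    fits: list[VariogramModel] = []
    for family in families:
        w = base_w
        try:
            fit = _fit_one_family(family, emp, w)
            if weighting == "cressie":
                # one reweighting pass: w = N(h) / gamma_model(h)^2
                pred = np.maximum(fit.semivariance(emp.lag_centers), 1e-12)
                fit = _fit_one_family(family, emp, base_w / pred ** 2)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("variogram fit failed for family %s: %s", family, exc)
            warnings.warn(f"variogram fit failed for family {family}: {exc}",
                          stacklevel=2)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("all variogram model fits failed")
    fits.sort(key=lambda m: (-m.r_squared, m.rss, _FAMILY_PREFERENCE[m.family]))
    return fits
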