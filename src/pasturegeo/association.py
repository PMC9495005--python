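"""Simple linear regressions between soil pH, forage mass, and spectral
indices.

The study design asks how much of the dry/green-matter variation each soil
or spectral variable explains: ordinary least squares with intercept, with
R-squared = 1 - SSres/SStot, fitted pairwise. Signed Pearson correlation is
reported alongside, since for simple OLS the direction of association is not
visible in R-squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: (predictor, response) pairs examined: three pH depths and the two indices
#: against each forage-mass variable.
DEFAULT_PAIRS = (
    list(product(["ph_0_20", "ph_20_30", "ph_30_40"], ["dm", "gm"]))
    + list(product(["ndvi", "ndwi"], ["dm", "gm"]))
)


@dataclass
class RegressionFit:
    """Simple OLS fit y = slope * x + intercept."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    r_squared: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a regression fit needs n >= 3")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


def fit_regression(x, y, x_name: str = "x", y_name: str = "y") -> RegressionFit:
    """Ordinary least squares of y on x (with intercept), listwise-complete.

    Raises if fewer than 3 complete pairs remain or x is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(
            f"need >= 3 complete pairs for {y_name} ~ {x_name}, have {len(x)}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {x_name!r} is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        x_name=x_name,
        y_name=y_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        r=float(res.rvalue),
        n=int(len(x)),
    )


def pairwise_report(table: pd.DataFrame,
                    pairs=None) -> pd.DataFrame:
    """Fit every examined (predictor, response) pair present in ``table``.

    Missing rows are dropped per pair (listwise per fit, not globally), with
    dropped counts logged. Pairs whose variables are absent, or whose fit is
    infeasible (too few pairs, constant predictor), are reported with NaN
    statistics rather than aborting the report.
    """
    if table.empty:
        raise ValueError("input table is empty")
    if pairs is None:
        pairs = DEFAULT_PAIRS
    rows = []
    for x_name, y_name in pairs:
        rec = {"x": x_name, "y": y_name, "slope": np.nan, "intercept": np.nan,
               "r_squared": np.nan, "r": np.nan, "n": 0}
        if x_name in table.columns and y_name in table.columns:
            sub = table[[x_name, y_name]].dropna()
            dropped = len(table) - len(sub)
            if dropped:
                logger.info("%s ~ %s: dropped %d incomplete rows",
                            y_name, x_name, dropped)
            try:
                fit = fit_regression(sub[x_name], sub[y_name], x_name, y_name)
                rec.update(slope=fit.slope, intercept=fit.intercept,
                           r_squared=fit.r_squared, r=fit.r, n=fit.n)
            except ValueError as exc:
                logger.warning("fit skipped: %s", exc)
        else:
            logger.warning("pair (%s, %s) not in table; skipped", x_name, y_name)
        rows.append(rec)
    return pd.DataFrame(rows)
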