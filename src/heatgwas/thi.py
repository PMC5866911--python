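"""Temperature-humidity index (THI) computation and heat-stress day classification.

The THI collapses dry-bulb temperature and relative humidity into a single
heat-load measure on the Celsius scale:

    THI(degC) = T - (0.55 - 0.0055 * RH) * (T - 14.5)

with T in degC and RH in percent (0-100).  Hourly THI values are summarised
per calendar day by their maximum, and days fall into four livestock
heat-stress categories at fixed thresholds:

    Normal    : max THI <  23.33 degC
    Alert     : 23.33 <= max THI < 26.11 degC
    Danger    : 26.11 <= max THI < 28.88 degC
    Emergency : max THI >= 28.88 degC

Lower bounds are inclusive, upper bounds exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: THI category labels in increasing heat-load order.
CATEGORIES: tuple[str, ...] = ("Normal", "Alert", "Danger", "Emergency")

#: Category boundaries in degC; lower-inclusive.
THRESHOLDS_C: tuple[float, ...] = (23.33, 26.11, 28.88)

#: Ordered contrast used when a category enters a linear model (Normal=0 ... Emergency=3).
CATEGORY_CONTRAST: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}


def compute_thi(temp_c, rh_pct):
    """Hourly temperature-humidity index in degC.

    Parameters
    ----------
    temp_c : float or array-like
        Dry-bulb (ambient) temperature in degC.
    rh_pct : float or array-like
        Relative humidity in percent, on the 0-100 scale.

    Returns
    -------
    float or ndarray
        THI in degC, evaluated exactly (no clamping).

    Raises
    ------
    ValueError
        If any relative humidity lies outside [0, 100].
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100) | ~np.isfinite(rh)):
        raise ValueError("relative humidity must lie in [0, 100] percent")
    thi = t - (0.55 - 0.0055 * rh) * (t - 14.5)
    if thi.ndim == 0:
        return float(thi)
    return thi


def classify_day(max_thi_c, thresholds: tuple[float, ...] = THRESHOLDS_C):
    """Assign the heat-stress category for a day's maximum THI.

    Boundaries are lower-inclusive: 23.33 -> Alert, 26.11 -> Danger,
    28.88 -> Emergency.
    """
    x = np.asarray(max_thi_c, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("max THI must be finite")
    idx = np.searchsorted(np.asarray(thresholds), x, side="right")
    cats = np.asarray(CATEGORIES, dtype=object)[idx]
    if x.ndim == 0:
        return str(cats)
    return cats


def categorize_series(
    weather: pd.DataFrame,
    min_hours: int = 18,
    thresholds: tuple[float, ...] = THRESHOLDS_C,
) -> pd.DataFrame:
    """Classify each calendar day of an hourly weather series.

    Parameters
    ----------
    weather : DataFrame
        Columns ``timestamp`` (datetime-like), ``temp_c``, ``rh_pct``.
    min_hours : int
        Days with fewer hourly records than this are dropped (and logged)
        rather than classified from partial coverage.

    Returns
    -------
    DataFrame
        Columns ``date``, ``max_thi_c``, ``category``; one row per retained day.
    """
    if len(weather) == 0:
        return pd.DataFrame(columns=["date", "max_thi_c", "category"])
    df = weather.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["thi"] = compute_thi(df["temp_c"].to_numpy(), df["rh_pct"].to_numpy())
    df["date"] = df["timestamp"].dt.date
    grp = df.groupby("date")["thi"].agg(max_thi_c="max", n_hours="count").reset_index()
    short = grp["n_hours"] < min_hours
    if short.any():
        logger.info(
            "dropping %d day(s) with fewer than %d hourly records",
            int(short.sum()), min_hours,
        )
    grp = grp.loc[~short].reset_index(drop=True)
    out = grp[["date", "max_thi_c"]].copy()
    out["category"] = classify_day(out["max_thi_c"].to_numpy(), thresholds)
    return out


@dataclass
class BarnModelFit:
    """Cubic regression of barn temperature on outdoor THI."""

    coef: np.ndarray          # polynomial coefficients, ascending powers 0..3
    adj_r2: float

    def predict(self, thi_c):
        x = np.asarray(thi_c, dtype=float)
        return sum(c * x**k for k, c in enumerate(self.coef))


def fit_barn_model(thi_c, barn_temp_c) -> BarnModelFit:
    """Fit barn temperature as a degree-3 polynomial in outdoor THI by OLS.

    Requires at least 5 pairs and a non-degenerate (non-constant) THI series.
    Returns the coefficients (ascending powers) and the adjusted R-squared.
    """
    x = np.asarray(thi_c, dtype=float)
    y = np.asarray(barn_temp_c, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("thi_c and barn_temp_c must be 1-D and of equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 (THI, barn temperature) pairs")
    design = np.vander(x, 4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate fit: THI series does not span a cubic design")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    p = 3
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return BarnModelFit(coef=coef, adj_r2=float(adj_r2))
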