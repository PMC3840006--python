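"""Regional extreme water-temperature model.

The thermal metric is Tmax7d: the maximum over July–September of the mean
temperature during 7 consecutive days, the usual standard for short-term
thermal tolerance in fish.  Water temperatures are predicted in two stages:

1. a regional air model regressing station Tmax7d-air on latitude and
   altitude, with year as a random intercept (stations within a year share a
   common anomaly); fitted defaults:
       Tmax7d_air = 323.25 - 6.914 * latitude - 0.0044 * altitude
2. basin-specific linear conversions Tmax7d-water ~ Tmax7d-air obtained from
   a mixed model with random intercept and slope by river basin; fitted
   default per-basin lines:
       Aragon:        3.372 + 0.656 * Tmax7d_air
       Arga-Ega:      4.688 + 0.589 * Tmax7d_air
       Bay of Biscay: 4.171 + 0.626 * Tmax7d_air
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .capacity import summer_window

# plausible geographic bounds for the regional model (warn outside)
LAT_BOUNDS = (40.0, 45.0)
ALT_BOUNDS = (0.0, 2500.0)


@dataclass(frozen=True)
class AirModelCoefficients:
    """Fixed effects of the regional Tmax7d-air model (+ year random SD)."""

    intercept: float = 323.25
    lat_slope: float = -6.914
    alt_slope: float = -0.0044
    year_sd: float = 0.0


@dataclass(frozen=True)
class WaterModelCoefficients:
    """Per-basin (intercept, slope) lines converting Tmax7d-air to water."""

    basins: dict = field(default_factory=lambda: {
        "Aragon": (3.372, 0.656),
        "Arga-Ega": (4.688, 0.589),
        "Bay of Biscay": (4.171, 0.626),
    })

    def __post_init__(self) -> None:
        for basin, (_, slope) in self.basins.items():
            if not 0 < slope < 1.5:
                raise ValueError(f"basin {basin}: slope {slope} outside (0, 1.5)")


def rolling_tmax7d(daily: pd.Series) -> float:
    """Max 7-day rolling mean over windows fully inside July 1 – Sept 30.

    ``daily`` is a date-indexed series.  Windows containing any missing day
    are skipped; if none survive, raises ValueError.
    """
    idx = pd.DatetimeIndex(daily.index)
    summer = daily[summer_window(idx)]
    if len(summer) < 7:
        raise ValueError("need at least 7 daily values inside July-September")
    # reindex on the calendar so gaps become NaN and poison their windows
    full = summer.reindex(pd.date_range(summer.index.min(), summer.index.max()))
    means = full.rolling(7).mean().dropna()
    if means.empty:
        raise ValueError("no complete 7-day window inside July-September")
    return float(means.max())


def predict_air_tmax7d(lat, alt, coeffs: AirModelCoefficients = AirModelCoefficients()):
    """Tmax7d-air (deg C) from latitude (decimal degrees) and altitude (m)."""
    lat = np.asarray(lat, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if np.any(lat < LAT_BOUNDS[0]) or np.any(lat > LAT_BOUNDS[1]):
        warnings.warn("latitude outside the regional model's fitted range")
    if np.any(alt < ALT_BOUNDS[0]) or np.any(alt > ALT_BOUNDS[1]):
        warnings.warn("altitude outside the regional model's fitted range")
    out = coeffs.intercept + coeffs.lat_slope * lat + coeffs.alt_slope * alt
    return float(out) if out.ndim == 0 else out


def predict_water_tmax7d(t_air, basin: str,
                         coeffs: WaterModelCoefficients = WaterModelCoefficients()):
    """Tmax7d-water (deg C) from Tmax7d-air via the basin-specific line."""
    if basin not in coeffs.basins:
        raise KeyError(
            f"unknown basin {basin!r}; known basins: {sorted(coeffs.basins)}")
    intercept, slope = coeffs.basins[basin]
    out = intercept + slope * np.asarray(t_air, dtype=float)
    return float(out) if out.ndim == 0 else out


def fit_regional_air_model(stations: pd.DataFrame) -> AirModelCoefficients:
    """Refit the air model: tmax7d_air ~ lat + alt, random intercept by year.

    ``stations`` needs columns lat, alt_m, year, tmax7d_air.  With a single
    year the random effect is unidentifiable and the fit reduces to OLS.
    """
    df = stations.dropna(subset=["lat", "alt_m", "year", "tmax7d_air"])
    if df["lat"].nunique() < 3:
        raise ValueError("need >= 3 distinct stations to fit the air model")
    X = sm.add_constant(df[["lat", "alt_m"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (lat/alt collinear)")
    if df["year"].nunique() < 2:
        res = sm.OLS(df["tmax7d_air"], X).fit()
        return AirModelCoefficients(res.params["const"], res.params["lat"],
                                    res.params["alt_m"], 0.0)
    model = smf.mixedlm("tmax7d_air ~ lat + alt_m", df, groups=df["year"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    year_sd = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    return AirModelCoefficients(float(res.params["Intercept"]),
                                float(res.params["lat"]),
                                float(res.params["alt_m"]), year_sd)


def fit_air_water_model(pairs: pd.DataFrame) -> WaterModelCoefficients:
    """Fit per-basin water~air lines from paired Tmax7d observations.

    ``pairs`` needs columns basin, tmax7d_air, tmax7d_water.  Fitted with a
    linear mixed model (random intercept and slope by basin); the returned
    per-basin lines are fixed effects plus basin BLUPs.  With a single basin
    the model falls back to simple regression with a warning.  On
    non-convergence, falls back to per-basin OLS lines.
    """
    df = pairs.dropna(subset=["basin", "tmax7d_air", "tmax7d_water"])
    basins = sorted(df["basin"].unique())
    if len(basins) < 2:
        warnings.warn("single basin: falling back to simple linear regression")
        res = sm.OLS(df["tmax7d_water"], sm.add_constant(df["tmax7d_air"])).fit()
        return WaterModelCoefficients(
            {basins[0]: (float(res.params["const"]), float(res.params["tmax7d_air"]))})
    for basin in basins:
        if (df["basin"] == basin).sum() < 3:
            raise ValueError(f"basin {basin!r} has fewer than 3 observations")
    try:
        model = smf.mixedlm("tmax7d_water ~ tmax7d_air", df, groups=df["basin"],
                            re_formula="~tmax7d_air")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        lines = {}
        for basin in basins:
            re = res.random_effects[basin]
            lines[basin] = (float(res.params["Intercept"] + re.iloc[0]),
                            float(res.params["tmax7d_air"] + re.iloc[1]))
    except Exception:
        warnings.warn("mixed model failed to converge; using per-basin OLS lines")
        lines = {}
        for basin in basins:
            sub = df[df["basin"] == basin]
            r = sm.OLS(sub["tmax7d_water"], sm.add_constant(sub["tmax7d_air"])).fit()
            lines[basin] = (float(r.params["const"]), float(r.params["tmax7d_air"]))
    return WaterModelCoefficients(lines)
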