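"""Carrying capacity from physical habitat via territory-size allometry.

Carrying capacity is defined as the maximum density a reach can support
during the period of minimum available physical habitat (summer): the mean
summer WUA of a life stage divided by the territory area an individual of
average body size of that stage defends,

    K_i = WUA_i / T_i      [trout / ha]

with the brown-trout territory allometry

    log10 T = (2.64 - 0.96 * age) * log10 L - (2.72 - 0.90 * age)

where T is territory area (m2 of WUA), L fork length (cm), and age is 0 for
young-of-the-year and 1 for juveniles and adults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitat import StageWUACurve

SUMMER_START = (7, 1)   # July 1
SUMMER_END = (9, 30)    # September 30, inclusive

#: age category entering the territory allometry per life stage
AGE_CATEGORY = {"yoy": 0, "juvenile": 1, "adult": 1}


@dataclass(frozen=True)
class TerritoryParams:
    """Coefficients of the territory-size allometry (log10 scale)."""

    slope_base: float = 2.64
    slope_age: float = 0.96
    intercept_base: float = 2.72
    intercept_age: float = 0.90


@dataclass(frozen=True)
class CapacityRecord:
    site_id: str
    year: int
    stage: str
    mean_summer_wua: float  # m2/ha
    mean_length: float      # cm
    territory: float        # m2
    K: float                # trout/ha


def territory_size(length_cm: float, age_category: int,
                   params: TerritoryParams = TerritoryParams()) -> float:
    """Territory area (m2 of WUA) for a fish of given length and age class."""
    if length_cm <= 0:
        raise ValueError("length must be > 0 cm")
    if age_category not in (0, 1):
        raise ValueError("age category must be 0 (YOY) or 1 (juvenile/adult)")
    slope = params.slope_base - params.slope_age * age_category
    intercept = params.intercept_base - params.intercept_age * age_category
    return float(10.0 ** (slope * np.log10(length_cm) - intercept))


def summer_window(dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask of days within July 1 – September 30 (inclusive)."""
    md = list(zip(dates.month, dates.day))
    return np.array([SUMMER_START <= m_d <= SUMMER_END for m_d in md])


def summer_mean_wua(curve: StageWUACurve, daily_q: pd.Series) -> float:
    """Mean daily WUA over the July–September window of a discharge series.

    ``daily_q`` is indexed by date; days outside the summer window are
    ignored.
    """
    idx = pd.DatetimeIndex(daily_q.index)
    mask = summer_window(idx)
    if not mask.any():
        raise ValueError("no daily discharge inside the July-September window")
    return float(np.mean(curve(daily_q.to_numpy()[mask])))


def carrying_capacity(wua: float, territory: float) -> float:
    """K = WUA / T (trout per ha); continuous, no rounding."""
    if territory <= 0:
        raise ValueError("territory must be > 0 m2")
    if wua < 0:
        raise ValueError("WUA must be >= 0")
    return wua / territory


def capacity_time_series(site_id: str, years, curves: dict,
                         daily_q: pd.Series, mean_lengths: dict,
                         params: TerritoryParams = TerritoryParams()) -> list[CapacityRecord]:
    """One CapacityRecord per year x stage for a site.

    ``mean_lengths`` maps (year, stage) -> mean fork length (cm) and
    ``curves`` maps stage -> StageWUACurve.  Discharge must cover each
    summer window.
    """
    idx = pd.DatetimeIndex(daily_q.index)
    records = []
    for year in years:
        in_year = daily_q[idx.year == year]
        for stage, curve in curves.items():
            key = (year, stage)
            if key not in mean_lengths:
                raise ValueError(
                    f"missing mean length for site {site_id}, year {year}, stage {stage}")
            wua = summer_mean_wua(curve, in_year)
            terr = territory_size(mean_lengths[key], AGE_CATEGORY[stage], params)
            records.append(CapacityRecord(site_id, int(year), stage, wua,
                                          mean_lengths[key], terr,
                                          carrying_capacity(wua, terr)))
    return records


def capacity_frame(records: list[CapacityRecord]) -> pd.DataFrame:
    """CapacityRecords as a tidy DataFrame (capacity.csv schema)."""
    return pd.DataFrame(
        [{"site_id": r.site_id, "year": r.year, "stage": r.stage,
          "mean_summer_wua": r.mean_summer_wua, "mean_length_cm": r.mean_length,
          "territory_m2": r.territory, "K_trout_per_ha": r.K} for r in records]
    )
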