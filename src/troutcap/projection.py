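"""Spatial projection of thermal suitability and thermal carrying capacity.

Given the regional air model and per-basin air-to-water conversions, every
grid cell (lat, alt, basin) receives an extreme water temperature
Tmax7d-water under a scenario air-warming offset delta_t_air.  A cell is
thermally suitable when Tmax7d-water is at or below the suitability
threshold (19.4 deg C by default).  The temperature-driven shortfall of
density relative to the habitat carrying capacity is obtained from the
fitted piecewise model: below the breakpoint the shortfall is zero; above
it the post-breakpoint decline component delta * (log10 T - log10 bp) on
the log10 residual scale is inverted to a percentage,

    reduction = (1 - 10 ** (delta * (log10 T - log10 bp))) * 100,

capped to [0, 100].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .limitation import PiecewiseFit
from .thermal import (AirModelCoefficients, WaterModelCoefficients,
                      predict_air_tmax7d, predict_water_tmax7d)

SUITABILITY_THRESHOLD_C = 19.4


def map_thermal_suitability(grid: pd.DataFrame,
                            air_coeffs: AirModelCoefficients = AirModelCoefficients(),
                            water_coeffs: WaterModelCoefficients = WaterModelCoefficients(),
                            delta_t_air: float = 0.0,
                            threshold_c: float = SUITABILITY_THRESHOLD_C) -> pd.DataFrame:
    """Attach t_water and suitability to a grid of cells.

    ``grid`` needs columns cell_id, lat, alt_m, basin.  Returns a copy with
    t_water and suitable columns; the suitable fraction is stored in
    ``result.attrs['suitable_fraction']``.
    """
    out = grid.copy()
    t_air = predict_air_tmax7d(out["lat"].to_numpy(), out["alt_m"].to_numpy(),
                               air_coeffs) + delta_t_air
    t_water = np.empty(len(out))
    for basin, sub in out.groupby("basin"):
        pos = out.index.get_indexer(sub.index)
        t_water[pos] = predict_water_tmax7d(
            np.asarray(t_air)[pos], basin, water_coeffs)
    out["t_water"] = t_water
    out["suitable"] = out["t_water"] <= threshold_c  # threshold inclusive
    out.attrs["suitable_fraction"] = float(out["suitable"].mean())
    return out


def project_thermal_capacity(grid: pd.DataFrame, fit: PiecewiseFit) -> pd.DataFrame:
    """Percent reduction of potential density below habitat capacity per cell.

    ``grid`` must already carry t_water (see map_thermal_suitability).
    """
    if fit is None:
        raise ValueError("a fitted piecewise model is required")
    out = grid.copy()
    log_t = np.log10(out["t_water"].to_numpy(dtype=float))
    excess = np.maximum(log_t - fit.breakpoint_log, 0.0)
    decline = fit.delta_slope * excess  # log10 density ratio below potential
    reduction = (1.0 - 10.0 ** decline) * 100.0
    out["reduction_pct"] = np.clip(reduction, 0.0, 100.0)
    return out


def scenario_table(grid: pd.DataFrame, fit: PiecewiseFit, deltas,
                   air_coeffs: AirModelCoefficients = AirModelCoefficients(),
                   water_coeffs: WaterModelCoefficients = WaterModelCoefficients(),
                   threshold_c: float = SUITABILITY_THRESHOLD_C) -> pd.DataFrame:
    """Suitable fraction and mean reduction across warming scenarios."""
    rows = []
    for dt in deltas:
        mapped = map_thermal_suitability(grid, air_coeffs, water_coeffs,
                                         delta_t_air=dt, threshold_c=threshold_c)
        proj = project_thermal_capacity(mapped, fit)
        rows.append({"delta_t_air": dt,
                     "suitable_fraction": mapped.attrs["suitable_fraction"],
                     "mean_reduction_pct": float(proj["reduction_pct"].mean()),
                     "max_reduction_pct": float(proj["reduction_pct"].max())})
    return pd.DataFrame(rows)
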