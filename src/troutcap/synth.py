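"""Synthetic study systems with the structure the analysis pipeline assumes.

The generator emulates a 12-year survey of ~51 stream sites in three river
basins spread along latitude/altitude gradients:

* site geometry: a mosaic of hydraulic cells with power-law depth/velocity
  rating curves and substrate/cover structure, scored by unimodal habitat
  selection curves per life stage;
* environment: daily discharge as a lognormal AR(1) process around a site
  median; extreme summer water temperature (Tmax7d-water) on the regional
  lat/alt air-temperature surface converted through basin-specific lines,
  plus year and site noise;
* population dynamics: stage-structured densities that saturate toward the
  habitat carrying capacity K (contest competition, Skellam-type
  recruitment), are knocked back by high emergence flows, and above a
  thermal breakpoint suffer a multiplicative penalty 10**(slope * (log10 T -
  log10 bp)) with site-level random slope heterogeneity (the penalty acts on
  realized density, never on K, so thermal capacity below habitat capacity
  is emergent in the analysis, not baked into its inputs);
* observation: three-pass removal electrofishing with constant capture
  probability.

All outputs are deterministic functions of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import capacity as cap
from . import drivers, thermal
from .habitat import STAGES, StreamCell, SuitabilityCurve, build_wua_discharge_curve


@dataclass
class BasinConfig:
    n_sites: int
    lat_range: tuple
    alt_range: tuple


@dataclass
class ScenarioConfig:
    """Default study conditions for the synthetic system."""

    n_years: int = 12
    start_year: int = 1993
    basins: dict = field(default_factory=lambda: {
        "Aragon": BasinConfig(19, (42.48, 42.95), (300.0, 895.0)),
        "Arga-Ega": BasinConfig(18, (42.55, 43.05), (250.0, 800.0)),
        "Bay of Biscay": BasinConfig(14, (43.00, 43.27), (40.0, 600.0)),
    })
    n_cells: int = 30
    site_area_ha_range: tuple = (0.05, 0.15)
    # discharge: lognormal AR(1) around a site median (m3/s)
    median_q_range: tuple = (0.4, 3.0)
    discharge_cv: float = 0.6
    discharge_rho: float = 0.85
    # temperature noise (deg C)
    year_effect_sd: float = 1.0
    air_noise_sd: float = 0.5
    water_noise_sd: float = 0.5
    # population model
    fecundity: float = 80.0          # effective YOY per adult before competition
    survival_yoy_juv: float = 0.85
    survival_juv_adult: float = 0.90
    survival_adult: float = 0.70
    saturation_sharpness: float = 4.0  # contest-competition abruptness (gamma)
    flow_mortality_coef: float = 0.08  # on Q_max7d above the historical median
    breakpoint_c: float = 19.4
    thermal_slopes: dict = field(default_factory=lambda: {
        "yoy": -12.80, "juvenile": -1.28, "adult": -2.94})  # per log10 deg C
    # lognormal site heterogeneity of the decline rate (CV 0.7 puts the
    # YOY site slope SD at ~9.0, the scale of the fitted random slopes)
    thermal_slope_site_cv: float = 0.7
    process_noise_cv: float = 0.20
    burn_in: int = 4
    # observation model
    capture_p: float = 0.5
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return sum(b.n_sites for b in self.basins.values())

    def __post_init__(self) -> None:
        if not 0 < self.capture_p <= 1:
            raise ValueError("capture probability must be in (0, 1]")
        if self.thermal_slope_site_cv < 0 or self.process_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    @property
    def years(self) -> list:
        return list(range(self.start_year, self.start_year + self.n_years))


# stage mean fork lengths (cm) and jitter used for the territory allometry
MEAN_LENGTH = {"yoy": 6.0, "juvenile": 13.0, "adult": 22.0}
LENGTH_SD = {"yoy": 0.3, "juvenile": 0.6, "adult": 1.0}


def _rng(cfg: ScenarioConfig, *key) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *key])


def default_hsc() -> dict:
    """Global habitat selection curves per stage (unimodal depth/velocity,
    categorical substrate/cover), with stage-shifted optima: young-of-the-
    year prefer shallow slow margins, adults deep moderate water."""
    depth = {
        "yoy": ([0.0, 0.05, 0.15, 0.35, 0.6, 1.0], [0.0, 0.5, 1.0, 1.0, 0.2, 0.0]),
        "juvenile": ([0.0, 0.25, 0.4, 0.7, 1.2, 2.0], [0.0, 0.05, 0.6, 1.0, 0.7, 0.3]),
        "adult": ([0.0, 0.35, 0.6, 1.0, 1.6, 2.8], [0.0, 0.05, 0.5, 1.0, 0.9, 0.5]),
    }
    velocity = {
        "yoy": ([0.0, 0.05, 0.2, 0.45, 0.8, 1.5], [0.8, 1.0, 0.9, 0.2, 0.02, 0.0]),
        "juvenile": ([0.0, 0.1, 0.4, 0.8, 1.5, 2.5], [0.3, 0.8, 1.0, 0.5, 0.1, 0.0]),
        "adult": ([0.0, 0.1, 0.5, 1.0, 1.8, 3.0], [0.4, 0.7, 1.0, 0.6, 0.2, 0.0]),
    }
    substrate = {
        "yoy": {1: 0.4, 2: 0.8, 3: 1.0, 4: 0.8, 5: 0.5, 6: 0.3},
        "juvenile": {1: 0.3, 2: 0.6, 3: 0.9, 4: 1.0, 5: 0.8, 6: 0.5},
        "adult": {1: 0.3, 2: 0.5, 3: 0.7, 4: 0.9, 5: 1.0, 6: 0.8},
    }
    cover = {
        "yoy": {0: 0.3, 1: 0.6, 2: 0.9, 3: 1.0},
        "juvenile": {0: 0.3, 1: 0.6, 2: 0.9, 3: 1.0},
        "adult": {0: 0.2, 1: 0.5, 2: 0.8, 3: 1.0},
    }
    out = {}
    for stage in STAGES:
        out[stage] = {
            "depth": SuitabilityCurve("depth", stage, tuple(depth[stage][0]),
                                      tuple(depth[stage][1])),
            "velocity": SuitabilityCurve("velocity", stage,
                                         tuple(velocity[stage][0]),
                                         tuple(velocity[stage][1])),
            "substrate": SuitabilityCurve("substrate", stage,
                                          categories=substrate[stage]),
            "cover": SuitabilityCurve("cover", stage, categories=cover[stage]),
        }
    return out


def generate_sites(cfg: ScenarioConfig):
    """Site table, per-site cell mosaics, habitat selection curves and
    stage mean lengths.

    Returns (sites, cells, hsc, mean_lengths): sites is a DataFrame
    (site_id, basin, lat, alt_m, reach_type, area_ha, median_q); cells maps
    site_id -> list[StreamCell]; hsc maps stage -> variable -> curve;
    mean_lengths is a DataFrame (site_id, year, stage, length_cm).
    """
    rng = _rng(cfg, 1)
    rows, cells = [], {}
    i = 0
    for basin, bc in cfg.basins.items():
        for _ in range(bc.n_sites):
            i += 1
            site_id = f"S{i:02d}"
            lat = rng.uniform(*bc.lat_range)
            alt = rng.uniform(*bc.alt_range)
            area_ha = rng.uniform(*cfg.site_area_ha_range)
            rows.append({"site_id": site_id, "basin": basin, "lat": lat,
                         "alt_m": alt,
                         "reach_type": rng.choice(["riffle-run", "pool-riffle"]),
                         "area_ha": area_ha,
                         "median_q": rng.uniform(*cfg.median_q_range)})
            # cell areas sum to the wetted site area
            raw = rng.lognormal(0.0, 0.4, size=cfg.n_cells)
            areas = raw / raw.sum() * area_ha * 10_000.0
            # site-level habitat quality: structural richness and hydraulic
            # scale differ between sites (this is what spreads K across the
            # site network); within-site jitter still mixes shallow slow
            # margin cells (YOY habitat) with deeper mid-channel cells
            p_good_sub = rng.uniform(0.05, 0.95)
            p_cover = rng.uniform(0.1, 0.95)
            depth_scale = rng.uniform(0.18, 0.38)
            vel_scale = rng.uniform(0.15, 0.45)
            cells[site_id] = [
                StreamCell(
                    cell_id=f"{site_id}C{j:02d}", area=float(areas[j]),
                    substrate=int(rng.choice([3, 4, 5]) if rng.random() < p_good_sub
                                  else rng.choice([1, 2, 6])),
                    cover=int(rng.binomial(3, p_cover)),
                    a_d=float(depth_scale * rng.lognormal(0.0, 0.55)),
                    b_d=float(rng.uniform(0.25, 0.5)),
                    a_v=float(vel_scale * rng.lognormal(0.0, 0.55)),
                    b_v=float(rng.uniform(0.2, 0.45)))
                for j in range(cfg.n_cells)]
    sites = pd.DataFrame(rows)
    ml = [{"site_id": s, "year": y, "stage": stage,
           "length_cm": float(MEAN_LENGTH[stage]
                              + rng.normal(0.0, LENGTH_SD[stage]))}
          for s in sites["site_id"] for y in cfg.years for stage in STAGES]
    return sites, cells, default_hsc(), pd.DataFrame(ml)


def generate_environment(cfg: ScenarioConfig, sites: pd.DataFrame):
    """Daily discharge series and annual Tmax7d temperatures per site.

    Returns (discharge, temps): discharge maps site_id -> daily pd.Series
    over the full study span; temps is a DataFrame (site_id, year,
    tmax7d_air, tmax7d_water).
    """
    rng = _rng(cfg, 2)
    dates = pd.date_range(f"{cfg.start_year}-01-01",
                          f"{cfg.years[-1]}-12-31", freq="D")
    sigma = float(np.sqrt(np.log(1.0 + cfg.discharge_cv**2)))
    rho = cfg.discharge_rho
    discharge = {}
    for site in sites.itertuples(index=False):
        z = np.empty(len(dates))
        z[0] = rng.normal(0.0, sigma)
        eps = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), size=len(dates) - 1)
        for t in range(1, len(dates)):
            z[t] = rho * z[t - 1] + eps[t - 1]
        discharge[site.site_id] = pd.Series(site.median_q * np.exp(z),
                                            index=dates)
    year_effect = {y: rng.normal(0.0, cfg.year_effect_sd) for y in cfg.years}
    temps = []
    for site in sites.itertuples(index=False):
        base_air = thermal.predict_air_tmax7d(site.lat, site.alt_m)
        for y in cfg.years:
            t_air = base_air + year_effect[y] + rng.normal(0.0, cfg.air_noise_sd)
            t_water = (thermal.predict_water_tmax7d(t_air, site.basin)
                       + rng.normal(0.0, cfg.water_noise_sd))
            temps.append({"site_id": site.site_id, "year": y,
                          "tmax7d_air": t_air, "tmax7d_water": t_water})
    return discharge, pd.DataFrame(temps)


def compute_capacities(cfg: ScenarioConfig, sites, cells, hsc, mean_lengths,
                       discharge, n_grid: int = 15) -> pd.DataFrame:
    """Run the habitat and capacity models over the generated system."""
    ml = {(r.site_id, r.year, r.stage): r.length_cm
          for r in mean_lengths.itertuples(index=False)}
    records = []
    for site in sites.itertuples(index=False):
        q = discharge[site.site_id]
        q_grid = np.quantile(q.to_numpy(), np.linspace(0.005, 0.995, n_grid))
        q_grid = np.unique(q_grid)
        curves = build_wua_discharge_curve(cells[site.site_id], hsc, q_grid)
        lengths = {(y, stage): ml[(site.site_id, y, stage)]
                   for y in cfg.years for stage in STAGES}
        records += cap.capacity_time_series(site.site_id, cfg.years, curves,
                                            q, lengths)
    return cap.capacity_frame(records)


def compute_flow_metrics(cfg: ScenarioConfig, sites, discharge) -> pd.DataFrame:
    """Standardized emergence flow metrics (Q_em, Q_max7d) per site x year."""
    rows = []
    for site in sites.itertuples(index=False):
        q = discharge[site.site_id]
        median = float(q.median())
        years_idx = pd.DatetimeIndex(q.index).year
        for y in cfg.years:
            q_em, q_max7d = drivers.standardized_emergence_flows(
                q[years_idx == y], median)
            rows.append({"site_id": site.site_id, "year": y,
                         "q_em": q_em, "q_max7d": q_max7d})
    return pd.DataFrame(rows)


def _saturate(b: float, k: float, gamma: float = 3.0) -> float:
    """Contest-competition saturation toward K.

    Maynard Smith-Slatkin form D = B / (1 + (B/K)**gamma)**(1/gamma):
    approximately linear in the flux B well below K, capped near K above it
    (territorial exclusion), with ``gamma`` controlling the abruptness.
    """
    if k <= 0:
        return 0.0
    u = b / k
    return b / (1.0 + u**gamma) ** (1.0 / gamma)


def step_densities(prev: dict, k_now: dict, cfg: ScenarioConfig,
                   thermal_factor: dict, flow_factor: float,
                   noise: dict) -> dict:
    """One year of the stage-structured recursion.

    ``prev`` holds last year's densities per stage, ``k_now`` this year's
    carrying capacities, ``thermal_factor``/``noise`` multiplicative factors
    per stage, ``flow_factor`` the emergence-flow survival multiplier on
    recruitment.
    """
    g = cfg.saturation_sharpness
    recruits = cfg.fecundity * prev["adult"]
    d_yoy = _saturate(recruits, k_now["yoy"], g) * flow_factor
    d_juv = _saturate(cfg.survival_yoy_juv * prev["yoy"], k_now["juvenile"], g)
    d_adu = _saturate(cfg.survival_juv_adult * prev["juvenile"]
                      + cfg.survival_adult * prev["adult"], k_now["adult"], g)
    out = {"yoy": d_yoy, "juvenile": d_juv, "adult": d_adu}
    return {s: out[s] * thermal_factor[s] * noise[s] for s in STAGES}


def simulate_population_dynamics(cfg: ScenarioConfig, capacities: pd.DataFrame,
                                 temps: pd.DataFrame,
                                 flows: pd.DataFrame) -> pd.DataFrame:
    """True stage-structured densities per site x year.

    Burn-in years recycle the first year's environment; the thermal penalty
    10**(slope_s * (log10 T - log10 bp)_+) uses a site-level random decline
    rate, lognormal around the stage slope, so every site declines above the
    breakpoint but at heterogeneous rates (the penalty never boosts density
    above its habitat-set level).
    """
    rng = _rng(cfg, 3)
    k = capacities.pivot_table(index=["site_id", "year"], columns="stage",
                               values="K_trout_per_ha")
    t_by = {(r.site_id, r.year): r.tmax7d_water
            for r in temps.itertuples(index=False)}
    fl = {(r.site_id, r.year): r.q_max7d for r in flows.itertuples(index=False)}
    sigma = float(np.sqrt(np.log(1.0 + cfg.process_noise_cv**2)))
    log_bp = np.log10(cfg.breakpoint_c)
    rows = []
    cv = cfg.thermal_slope_site_cv
    slope_sigma = float(np.sqrt(np.log(1.0 + cv**2))) if cv > 0 else 0.0
    for site_id in capacities["site_id"].unique():
        site_slopes = {
            s: cfg.thermal_slopes[s]
               * float(rng.lognormal(-slope_sigma**2 / 2.0, slope_sigma))
            for s in STAGES}
        first = cfg.years[0]
        k0 = {s: k.loc[(site_id, first), s] for s in STAGES}
        dens = dict(k0)  # start at first-year K
        schedule = [first] * cfg.burn_in + cfg.years
        for j, year in enumerate(schedule):
            k_now = {s: k.loc[(site_id, year), s] for s in STAGES}
            excess = max(0.0, np.log10(t_by[(site_id, year)]) - log_bp)
            therm = {s: 10.0 ** (site_slopes[s] * excess) for s in STAGES}
            flow = float(np.exp(-cfg.flow_mortality_coef
                                * max(0.0, fl[(site_id, year)] - 1.0)))
            noise = {s: float(rng.lognormal(-sigma**2 / 2.0, sigma))
                     for s in STAGES} if sigma > 0 else {s: 1.0 for s in STAGES}
            dens = step_densities(dens, k_now, cfg, therm, flow, noise)
            if j >= cfg.burn_in:
                for s in STAGES:
                    rows.append({"site_id": site_id, "year": year, "stage": s,
                                 "density": dens[s]})
    return pd.DataFrame(rows)


def simulate_removal_sampling(true_densities: pd.DataFrame, sites: pd.DataFrame,
                              p: float, seed: int) -> pd.DataFrame:
    """Three-pass binomial removal sampling of the true densities."""
    if not 0 < p <= 1:
        raise ValueError("capture probability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    area = dict(zip(sites["site_id"], sites["area_ha"]))
    rows = []
    for r in true_densities.itertuples(index=False):
        n = int(round(r.density * area[r.site_id]))
        remaining = n
        catches = []
        for _ in range(3):
            c = int(rng.binomial(remaining, p)) if remaining > 0 else 0
            catches.append(c)
            remaining -= c
        rows.append({"site_id": r.site_id, "year": r.year, "stage": r.stage,
                     "pass1": catches[0], "pass2": catches[1],
                     "pass3": catches[2], "site_area_ha": area[r.site_id]})
    return pd.DataFrame(rows)


def generate_dataset(cfg: ScenarioConfig | None = None) -> dict:
    """Generate a complete synthetic study system.

    Returns a dict with keys sites, cells, hsc, mean_lengths, discharge,
    temps, capacity, flows, true_densities, catches, config.
    """
    cfg = cfg or ScenarioConfig()
    sites, cells, hsc, mean_lengths = generate_sites(cfg)
    discharge, temps = generate_environment(cfg, sites)
    capacity = compute_capacities(cfg, sites, cells, hsc, mean_lengths, discharge)
    flows = compute_flow_metrics(cfg, sites, discharge)
    true_densities = simulate_population_dynamics(cfg, capacity, temps, flows)
    catches = simulate_removal_sampling(
        true_densities, sites, cfg.capture_p,
        seed=int(np.random.default_rng([cfg.seed, 4]).integers(0, 2**31 - 1)))
    return {"sites": sites, "cells": cells, "hsc": hsc,
            "mean_lengths": mean_lengths, "discharge": discharge,
            "temps": temps, "capacity": capacity, "flows": flows,
            "true_densities": true_densities, "catches": catches,
            "config": cfg}


def simulate_piecewise_residuals(n_sites: int = 51, n_years: int = 12,
                                 breakpoint_c: float = 19.4,
                                 pre_slope: float = 0.0,
                                 post_delta: float = -12.8,
                                 sd_pre: float = 3.9, sd_post: float = 9.2,
                                 noise_sd: float = 0.10,
                                 temp_range: tuple = (15.0, 22.0),
                                 within_site_sd: float = 0.8,
                                 seed: int = 0) -> pd.DataFrame:
    """Residual-scale data from a known broken-stick mixed model.

    r = a_i + (pre + u_i) * x + (post_delta + w_i) * (x - x_bp)_+ + eps,
    x = log10 T; used for parameter-recovery checks of the piecewise fit.
    """
    rng = np.random.default_rng(seed)
    x_bp = np.log10(breakpoint_c)
    rows = []
    for i in range(n_sites):
        mu_t = rng.uniform(*temp_range)
        a_i = rng.normal(0.0, 0.05)
        u_i = rng.normal(0.0, sd_pre)
        w_i = rng.normal(0.0, sd_post)
        for y in range(n_years):
            t = max(10.0, mu_t + rng.normal(0.0, within_site_sd))
            x = np.log10(t)
            r = (a_i + (pre_slope + u_i) * (x - x_bp)
                 + (post_delta + w_i) * max(0.0, x - x_bp)
                 + rng.normal(0.0, noise_sd))
            rows.append({"site_id": f"S{i:02d}", "year": y, "log_t": x, "r": r})
    return pd.DataFrame(rows)
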