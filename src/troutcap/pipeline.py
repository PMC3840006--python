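"""End-to-end analysis: removal estimation -> density drivers -> thermal
limitation -> warming projection, over a (synthetic or observed) dataset."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import drivers, limitation, popest, projection
from .habitat import STAGES


def estimate_densities(catches: pd.DataFrame) -> pd.DataFrame:
    """Zippin/Seber density estimates for every removal sample.

    Samples whose catch pattern admits no estimate are dropped; their count
    is stored in ``result.attrs['n_no_estimate']``.
    """
    rows, dropped = [], 0
    for r in catches.itertuples(index=False):
        sample = popest.RemovalSample(r.site_id, int(r.year), r.stage,
                                      int(r.pass1), int(r.pass2), int(r.pass3),
                                      float(r.site_area_ha))
        try:
            est = popest.density_estimate(sample)
        except popest.NoEstimateError:
            dropped += 1
            continue
        rows.append({"site_id": est.site_id, "year": est.year,
                     "stage": est.stage, "density": est.density,
                     "density_var": est.density_var, "p_hat": est.p_hat})
    out = pd.DataFrame(rows)
    out.attrs["n_no_estimate"] = dropped
    return out


@dataclass
class StageResult:
    stage: str
    table: pd.DataFrame
    forest: drivers.ForestFit
    importance: pd.Series
    residuals: pd.DataFrame
    ctt: tuple | None
    piecewise: limitation.PiecewiseFit | None


def analyse_stage(stage: str, densities: pd.DataFrame, capacity: pd.DataFrame,
                  flows: pd.DataFrame, temps: pd.DataFrame, seed: int,
                  mtry: int = drivers.DEFAULT_MTRY,
                  ntree: int = drivers.DEFAULT_NTREE,
                  fit_piecewise: bool = True) -> StageResult:
    """Drivers model + thermal limitation for one life stage."""
    table = drivers.build_predictor_table(densities, capacity, flows, stage)
    forest = drivers.fit_density_forest(table, mtry=mtry, ntree=ntree, seed=seed)
    importance = drivers.permutation_importance(forest, seed=seed + 1)
    obs = table[["site_id", "year"]].copy()
    obs["stage"] = stage
    obs["density"] = forest.y_
    obs["predicted"] = forest.oob_predictions
    obs = obs.merge(temps[["site_id", "year", "tmax7d_water"]],
                    on=["site_id", "year"], how="left")
    residuals = limitation.residual_frame(limitation.relative_residuals(obs))
    ctt = limitation.detect_ctt(residuals)
    pw = None
    if fit_piecewise:
        try:
            pw = limitation.fit_piecewise_lme(residuals)
        except Exception as exc:  # pragma: no cover - diagnostic path
            warnings.warn(f"piecewise fit failed for {stage}: {exc}")
    return StageResult(stage, table, forest, importance, residuals, ctt, pw)


def aggregate_population_residuals(stage_results: dict) -> pd.DataFrame:
    """All-stage population model input: observed and predicted densities
    summed over stages before the residual transform."""
    obs = None
    for stage, res in stage_results.items():
        part = res.table[["site_id", "year"]].copy()
        part[f"d_{stage}"] = res.forest.y_
        part[f"p_{stage}"] = res.forest.oob_predictions
        obs = part if obs is None else obs.merge(part, on=["site_id", "year"])
    obs = obs.dropna()
    out = obs[["site_id", "year"]].copy()
    out["density"] = sum(obs[f"d_{s}"] for s in stage_results)
    out["predicted"] = sum(obs[f"p_{s}"] for s in stage_results)
    out["stage"] = "population"
    return out


def run_pipeline(dataset: dict, seed: int = 0,
                 scenario_deltas=(0.0, 1.5, 3.0, 4.5),
                 fit_piecewise: bool = True) -> dict:
    """Full analysis over a generated dataset (see synth.generate_dataset)."""
    densities = estimate_densities(dataset["catches"])
    temps = dataset["temps"]
    results = {}
    for stage in STAGES:
        results[stage] = analyse_stage(stage, densities, dataset["capacity"],
                                       dataset["flows"], temps, seed=seed,
                                       fit_piecewise=fit_piecewise)
    pop_obs = aggregate_population_residuals(results)
    pop_obs = pop_obs.merge(temps[["site_id", "year", "tmax7d_water"]],
                            on=["site_id", "year"], how="left")
    pop_res = limitation.residual_frame(limitation.relative_residuals(pop_obs))
    pop_pw = None
    if fit_piecewise:
        try:
            pop_pw = limitation.fit_piecewise_lme(pop_res)
        except Exception as exc:  # pragma: no cover
            warnings.warn(f"population piecewise fit failed: {exc}")
    # project on the site network as the spatial grid
    grid = dataset["sites"][["site_id", "lat", "alt_m", "basin"]].rename(
        columns={"site_id": "cell_id"})
    scen = None
    ref_fit = pop_pw or next((r.piecewise for r in results.values()
                              if r.piecewise), None)
    if ref_fit is not None:
        scen = projection.scenario_table(grid, ref_fit, scenario_deltas)
    return {"densities": densities, "stages": results,
            "population_residuals": pop_res, "population_piecewise": pop_pw,
            "scenarios": scen}
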