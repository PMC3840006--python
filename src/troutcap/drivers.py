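"""Density-driver inference: predictor construction and random-forest models.

Density of a life stage x in year i is regressed on the predictors of the
study design: its carrying capacity K_x,i; the carrying-capacity saturation
(D/K ratio, a proxy for competition intensity) its cohort experienced the
previous year at age x-1; the D/K ratios of accompanying life stages in year
i; the relative capacity ratio K_x,i / K_{x-1,i-1} across the ontogenetic
transition; and two standardized emergence-period (March-April) flow metrics
(Q_em, Q_max7d, both divided by the historical median daily discharge).

The regression learner is a random forest of CART trees, fitted with
bootstrap bagging; each tree's out-of-bag (OOB) rows provide an unbiased
generalization error used for tuning (ntree, mtry), for the reported
explained variance (OOB R^2 = 1 - MSE_OOB / var(y)), and for per-tree
permutation importance (%IncMSE).  The forest is built explicitly over
sklearn decision trees so that per-tree bootstrap membership is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

EMERGENCE_START = (3, 1)   # March 1
EMERGENCE_END = (4, 30)    # April 30, inclusive

#: (previous-stage, accompanying stages) per modelled stage
STAGE_STRUCTURE = {
    "yoy": ("adult", ("juvenile", "adult")),
    "juvenile": ("yoy", ("yoy", "adult")),
    "adult": ("juvenile", ("yoy", "juvenile")),
}

#: replication-mode forest settings
DEFAULT_MTRY = 3
DEFAULT_NTREE = 600


def emergence_window(dates: pd.DatetimeIndex) -> np.ndarray:
    md = list(zip(dates.month, dates.day))
    return np.array([EMERGENCE_START <= m_d <= EMERGENCE_END for m_d in md])


def standardized_emergence_flows(daily_q: pd.Series,
                                 historical_median_q: float) -> tuple[float, float]:
    """(Q_em, Q_max7d) for one year's March-April discharge.

    Q_em is the window mean and Q_max7d the maximum 7-day rolling mean, both
    divided by the historical median daily discharge of the site.
    """
    if historical_median_q <= 0:
        raise ValueError("historical median discharge must be > 0")
    idx = pd.DatetimeIndex(daily_q.index)
    window = daily_q[emergence_window(idx)]
    if window.empty:
        raise ValueError("no discharge values in the March-April window")
    q_em = float(window.mean()) / historical_median_q
    if len(window) < 7:
        raise ValueError("need >= 7 days in the emergence window for Q_max7d")
    full = window.reindex(pd.date_range(window.index.min(), window.index.max()))
    means = full.rolling(7).mean().dropna()
    if means.empty:
        raise ValueError("no complete 7-day window in March-April")
    return q_em, float(means.max()) / historical_median_q


def saturation_ratio(density: float, k: float) -> float:
    """D/K ratio; may exceed 1.  Undefined (nan) when K = 0 with D > 0."""
    if k > 0:
        return density / k
    return 0.0 if density == 0 else float("nan")


def build_predictor_table(densities: pd.DataFrame, capacities: pd.DataFrame,
                          flows: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Assemble the stage-specific modelling table.

    Inputs are tidy frames: ``densities`` (site_id, year, stage, density),
    ``capacities`` (site_id, year, stage, K_trout_per_ha), ``flows``
    (site_id, year, q_em, q_max7d).  The first year per site is dropped
    (lagged predictors undefined); rows with an undefined D/K (K = 0) are
    excluded, with the count stored in ``table.attrs['n_dropped']``.
    """
    if stage not in STAGE_STRUCTURE:
        raise ValueError(f"unknown stage {stage!r}")
    prev_stage, accompanying = STAGE_STRUCTURE[stage]
    d = densities.pivot_table(index=["site_id", "year"], columns="stage",
                              values="density")
    k = capacities.pivot_table(index=["site_id", "year"], columns="stage",
                               values="K_trout_per_ha")
    for s in (stage, prev_stage) + accompanying:
        if s not in d.columns or s not in k.columns:
            raise ValueError(f"missing density or capacity series for stage {s!r}")
    dk = d / k  # saturation ratios, elementwise
    rows = []
    n_dropped = 0
    for site_id, site_d in d.groupby(level="site_id"):
        years = sorted(site_d.index.get_level_values("year"))
        for year in years[1:]:  # first year has no lags
            prev = (site_id, year - 1)
            cur = (site_id, year)
            if prev not in d.index:
                continue
            row = {
                "site_id": site_id, "year": year,
                "K": k.loc[cur, stage],
                "past_dk": dk.loc[prev, prev_stage],
                f"dk_{accompanying[0]}": dk.loc[cur, accompanying[0]],
                f"dk_{accompanying[1]}": dk.loc[cur, accompanying[1]],
                "k_ratio": k.loc[cur, stage] / k.loc[prev, prev_stage]
                if k.loc[prev, prev_stage] > 0 else np.nan,
                "density": d.loc[cur, stage],
            }
            fl = flows[(flows["site_id"] == site_id) & (flows["year"] == year)]
            if fl.empty:
                raise ValueError(f"missing flow metrics for {site_id} year {year}")
            row["q_em"] = float(fl["q_em"].iloc[0])
            row["q_max7d"] = float(fl["q_max7d"].iloc[0])
            if any(not np.isfinite(v) for kk, v in row.items()
                   if kk not in ("site_id", "year")):
                n_dropped += 1
                continue
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["n_dropped"] = n_dropped
    table.attrs["stage"] = stage
    table.attrs["predictors"] = ["K", "past_dk", f"dk_{accompanying[0]}",
                                 f"dk_{accompanying[1]}", "k_ratio",
                                 "q_em", "q_max7d"]
    return table


@dataclass
class ForestFit:
    """A fitted bagged forest with OOB bookkeeping."""

    stage: str
    mtry: int
    ntree: int
    predictors: list
    trees: list = field(repr=False, default_factory=list)
    inbag: list = field(repr=False, default_factory=list)  # bootstrap indices per tree
    oob_predictions: np.ndarray | None = None
    oob_mse: float = float("nan")
    oob_r2: float = float("nan")
    X_: np.ndarray | None = field(repr=False, default=None)
    y_: np.ndarray | None = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees], axis=0)


def _grow_forest(X, y, mtry, ntree, rng):
    n = len(y)
    trees, inbag = [], []
    for _ in range(ntree):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag.append(idx)
    return trees, inbag


def _oob_error_curve(X, y, trees, inbag, ntree_grid):
    """OOB MSE after the first n trees, for each n in ntree_grid."""
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    out = {}
    grid = sorted(ntree_grid)
    gi = 0
    for t, (tree, idx) in enumerate(zip(trees, inbag), start=1):
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size:
            sums[oob] += tree.predict(X[oob])
            counts[oob] += 1
        if gi < len(grid) and t == grid[gi]:
            seen = counts > 0
            pred = np.full(n, np.nan)
            pred[seen] = sums[seen] / counts[seen]
            out[t] = float(np.mean((y[seen] - pred[seen]) ** 2))
            gi += 1
    return out


def tune_random_forest(table: pd.DataFrame, mtry_grid=None, ntree_grid=None,
                       seed: int = 0) -> tuple[int, int]:
    """Grid-search (mtry, ntree) minimizing the OOB mean squared error.

    For each mtry one forest of max(ntree_grid) trees is grown and the OOB
    error evaluated at every ntree in the grid from its leading trees.
    Deterministic given ``seed``.
    """
    predictors = table.attrs["predictors"]
    if len(table) < 30:
        raise ValueError("need >= 30 rows to tune the forest")
    y = table["density"].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("degenerate response: zero variance")
    X = table[predictors].to_numpy(dtype=float)
    mtry_grid = list(mtry_grid) if mtry_grid is not None else list(
        range(1, len(predictors) + 1))
    ntree_grid = list(ntree_grid) if ntree_grid is not None else list(
        range(100, 1001, 100))
    best = None
    for mtry in mtry_grid:
        rng = np.random.default_rng([seed, mtry])
        trees, inbag = _grow_forest(X, y, mtry, max(ntree_grid), rng)
        for ntree, err in _oob_error_curve(X, y, trees, inbag, ntree_grid).items():
            if best is None or err < best[0]:
                best = (err, mtry, ntree)
    return best[1], best[2]


def fit_density_forest(table: pd.DataFrame, mtry: int = DEFAULT_MTRY,
                       ntree: int = DEFAULT_NTREE, seed: int = 0) -> ForestFit:
    """Fit the bagged forest and compute OOB predictions and OOB R^2."""
    predictors = table.attrs["predictors"]
    y = table["density"].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("degenerate response: zero variance")
    X = table[predictors].to_numpy(dtype=float)
    if not 1 <= mtry <= len(predictors):
        raise ValueError("mtry must be in [1, n_predictors]")
    rng = np.random.default_rng([seed, mtry])
    trees, inbag = _grow_forest(X, y, mtry, ntree, rng)
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, idx in zip(trees, inbag):
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size:
            sums[oob] += tree.predict(X[oob])
            counts[oob] += 1
    seen = counts > 0
    oob_pred = np.full(n, np.nan)
    oob_pred[seen] = sums[seen] / counts[seen]
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
    fit = ForestFit(stage=table.attrs.get("stage", "?"), mtry=mtry, ntree=ntree,
                    predictors=list(predictors), trees=trees, inbag=inbag,
                    oob_predictions=oob_pred, oob_mse=oob_mse,
                    oob_r2=1.0 - oob_mse / float(np.var(y)),
                    X_=X, y_=y)
    return fit


def permutation_importance(fit: ForestFit, seed: int = 0) -> pd.Series:
    """%IncMSE per predictor.

    For each tree, the MSE on its OOB rows is recomputed after permuting one
    predictor's OOB values; the increase is averaged over trees and expressed
    as a percentage of the mean per-tree OOB MSE.
    """
    rng = np.random.default_rng(seed)
    X, y = fit.X_, fit.y_
    n = len(y)
    p = len(fit.predictors)
    increases = np.zeros(p)
    base_total = 0.0
    n_trees_used = 0
    for tree, idx in zip(fit.trees, fit.inbag):
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size < 2:
            continue
        Xo = X[oob]
        base = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        base_total += base
        n_trees_used += 1
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            increases[j] += np.mean((y[oob] - tree.predict(Xp)) ** 2) - base
    mean_base = base_total / n_trees_used
    pct = 100.0 * (increases / n_trees_used) / mean_base
    return pd.Series(pct, index=fit.predictors).sort_values(ascending=False)


def partial_dependence(fit: ForestFit, predictor: str, grid=None) -> pd.DataFrame:
    """Marginal effect of one predictor: mean prediction over the data with
    the predictor fixed at each grid value (grid defaults to in-range
    percentiles 5..95)."""
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} not a model predictor")
    j = fit.predictors.index(predictor)
    col = fit.X_[:, j]
    if grid is None:
        grid = np.quantile(col, np.linspace(0.05, 0.95, 25))
    grid = np.asarray(grid, dtype=float)
    lo, hi = col.min(), col.max()
    curve = np.empty(grid.size)
    for i, g in enumerate(grid):
        Xg = fit.X_.copy()
        Xg[:, j] = g
        curve[i] = float(np.mean(fit.predict(Xg)))
    return pd.DataFrame({"x": grid, "pd": curve,
                         "extrapolated": (grid < lo) | (grid > hi)})
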