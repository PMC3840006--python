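"""Thermal limitation of density: quantile regression, critical temperature
thresholds and piecewise mixed-effects breakpoint models.

The response throughout is the relative residual of observed density from
the habitat-driven (random forest, out-of-bag) prediction,

    x = (observed - predicted) / predicted,    r = log10(x + 1),

regressed on log10 of the extreme water temperature Tmax7d-water.  Because
quantile regression estimates rates of change at any part of the response
distribution, a limiting factor shows up as upper quantiles declining with
temperature while lower quantiles decline faster (unequal variation).

Two threshold summaries complement the quantile fits:

* CTT (critical temperature threshold): the temperature beyond which no
  positive residuals exist, i.e. observed density never exceeds the
  habitat-based prediction.
* A continuous broken-stick ("piecewise") linear mixed model
  r ~ 1 + t + (t - bp)_+ with random intercept and segment slopes by site,
  the breakpoint chosen by profile likelihood over a grid in deg C (the
  regression itself runs on the log10 temperature scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg
import statsmodels.api as sm

ZERO_DENSITY_FLOOR = 1e-6  # x floored to -1 + this when observed density is 0
DEFAULT_TAUS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class ThermalResidual:
    site_id: str
    year: int
    stage: str
    log_t: float  # log10 Tmax7d-water
    r: float      # log10(x + 1)
    flagged: bool = False


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    intercept: float
    slope: float
    intercept_ci: tuple
    slope_ci: tuple
    n_boot: int
    slope_boot: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint_c: float          # deg C
    breakpoint_log: float        # log10 deg C
    pre_slope: float
    pre_slope_se: float
    pre_slope_t: float
    pre_slope_p: float
    post_slope: float            # total slope above bp = pre + delta
    delta_slope: float           # coefficient of (t - bp)_+
    delta_slope_se: float
    delta_slope_t: float
    delta_slope_p: float
    intercept: float
    sd_intercept: float
    sd_pre_slope: float
    sd_post_slope: float
    loglik: float
    lrt_stat: float              # vs single-line model, same random structure
    lrt_p: float
    n: int
    converged: bool


def relative_residuals(observed: pd.DataFrame) -> list[ThermalResidual]:
    """Relative residuals from observed vs (OOB-)predicted densities.

    ``observed`` needs columns site_id, year, stage, density, predicted,
    tmax7d_water.  Rows with predicted <= 0 are dropped (flagged in the
    returned list's complement count via attrs is not kept; they are simply
    skipped).  Observed zero densities are floored to x = -1 + 1e-6 and
    flagged.
    """
    out = []
    for row in observed.itertuples(index=False):
        if not np.isfinite(row.predicted) or row.predicted <= 0:
            continue
        x = (row.density - row.predicted) / row.predicted
        flagged = False
        if row.density == 0:
            x = -1.0 + ZERO_DENSITY_FLOOR
            flagged = True
        out.append(ThermalResidual(row.site_id, int(row.year), row.stage,
                                   float(np.log10(row.tmax7d_water)),
                                   float(np.log10(x + 1.0)), flagged))
    return out


def residual_frame(residuals) -> pd.DataFrame:
    return pd.DataFrame([{"site_id": t.site_id, "year": t.year, "stage": t.stage,
                          "log_t": t.log_t, "r": t.r, "flagged": t.flagged}
                         for t in residuals])


def _qr_fit(x, y, tau):
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(y, X).fit(q=tau)
    return float(res.params[0]), float(res.params[1])


def quantile_regression_suite(residuals: pd.DataFrame, taus=DEFAULT_TAUS,
                              n_boot: int = 1000, seed: int = 0,
                              min_n: int = 50) -> list[QuantileFit]:
    """Linear quantile regressions of r on log_t with bootstrap CIs.

    Case-resampling bootstrap (site x year rows resampled with replacement);
    percentile 95% CIs.  The bootstrap slope draws are kept on each fit so
    cross-tau slope differences can be tested with
    :func:`slope_difference_ci`.
    """
    x = residuals["log_t"].to_numpy(dtype=float)
    y = residuals["r"].to_numpy(dtype=float)
    n = len(y)
    if n < min_n:
        raise ValueError(f"need >= {min_n} observations, got {n}")
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    fits = []
    for tau in taus:
        b0, b1 = _qr_fit(x, y, tau)
        slopes = np.empty(n_boot)
        icepts = np.empty(n_boot)
        for b in range(n_boot):
            idx = boot_idx[b]
            icepts[b], slopes[b] = _qr_fit(x[idx], y[idx], tau)
        fits.append(QuantileFit(
            tau=tau, intercept=b0, slope=b1,
            intercept_ci=(float(np.percentile(icepts, 2.5)),
                          float(np.percentile(icepts, 97.5))),
            slope_ci=(float(np.percentile(slopes, 2.5)),
                      float(np.percentile(slopes, 97.5))),
            n_boot=n_boot, slope_boot=slopes))
    return fits


def slope_difference_ci(fit_a: QuantileFit, fit_b: QuantileFit,
                        level: float = 0.95) -> tuple[float, float, float]:
    """(difference, lo, hi): bootstrap CI of slope(tau_a) - slope(tau_b).

    Uses the paired bootstrap draws (same resamples across taus).
    """
    diff = fit_a.slope - fit_b.slope
    draws = fit_a.slope_boot - fit_b.slope_boot
    alpha = (1.0 - level) / 2.0
    return (diff, float(np.percentile(draws, 100 * alpha)),
            float(np.percentile(draws, 100 * (1 - alpha))))


def detect_ctt(residuals: pd.DataFrame, min_tail: int = 5):
    """Critical temperature threshold: smallest observed log_t above which
    every residual is non-positive, with at least ``min_tail`` observations
    in the tail.

    Returns (ctt_log10, ctt_deg_c, n_tail), or None when positive residuals
    persist at the maximum temperature (threshold undefined).
    """
    df = residuals.sort_values("log_t", ascending=False)
    log_t = df["log_t"].to_numpy()
    r = df["r"].to_numpy()
    if len(r) == 0:
        raise ValueError("no residuals supplied")
    if r[0] > 0:
        return None
    best = None
    all_nonpos = True
    for i in range(len(r)):
        if r[i] > 0:
            break
        # candidate threshold at this observation if the tail is large enough
        tail_n = i + 1
        # include ties: all observations at the same log_t must be in the tail
        if i + 1 < len(r) and log_t[i + 1] == log_t[i]:
            continue
        if tail_n >= min_tail:
            best = (float(log_t[i]), tail_n)
    if best is None:
        return None
    t_star, n_tail = best
    return t_star, float(10.0 ** t_star), n_tail


def _fit_lmm(df: pd.DataFrame, with_break: bool, random_structure: str):
    """One ML fit of the (piecewise) linear mixed model.

    random_structure: "full" = random intercept + both segment slopes
    (independent variance components), "slope" = intercept + post-segment
    slope, "intercept" = intercept only.
    """
    fixed = "r ~ log_t + t_bp" if with_break else "r ~ log_t"
    vc = {}
    if random_structure == "full":
        vc = {"log_t": "0 + log_t"}
        if with_break:
            vc["t_bp"] = "0 + t_bp"
    elif random_structure == "slope" and with_break:
        vc = {"t_bp": "0 + t_bp"}
    model = smf.mixedlm(fixed, df, groups=df["site_id"], re_formula="1",
                        vc_formula=vc if vc else None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs")
    return res


def _with_knot(df, bp_c):
    d = df.copy()
    d["t_bp"] = np.maximum(d["log_t"] - np.log10(bp_c), 0.0)
    return d


def _side_support_ok(d) -> bool:
    # demand real support on both sides of the knot (min 5 obs and 10% of
    # rows) to exclude degenerate edge breakpoints, as is standard for
    # segmented regression
    need = max(5, int(np.ceil(0.10 * len(d))))
    return (d["t_bp"] > 0).sum() >= need and (d["t_bp"] == 0).sum() >= need


def _profile_loglik(df, bp_c, random_structure):
    d = _with_knot(df, bp_c)
    if not _side_support_ok(d):
        return None, -np.inf
    try:
        res = _fit_lmm(d, True, random_structure)
    except Exception:
        return None, -np.inf
    ll = float(res.llf)
    # MixedLM reports llf = +inf when a variance component collapses to the
    # boundary; treat such fits as unusable for likelihood comparison
    return res, (ll if np.isfinite(ll) else -np.inf)


def _search_loglik(df, bp_c) -> float:
    """Breakpoint-search objective: profile likelihood of the fixed-effects
    analogue (site fixed intercepts), which is always finite and carries the
    same fixed-kink information as the mixed model."""
    d = _with_knot(df, bp_c)
    if not _side_support_ok(d):
        return -np.inf
    try:
        res = smf.ols("r ~ C(site_id) + log_t + t_bp", d).fit()
    except Exception:
        return -np.inf
    return float(res.llf)


def fit_piecewise_lme(residuals: pd.DataFrame, breakpoint_grid=None,
                      min_sites: int = 10, min_years: int = 5) -> PiecewiseFit:
    """Broken-stick mixed model with profile-likelihood breakpoint search.

    ``residuals`` needs columns site_id, log_t, r.  The fixed structure is
    r ~ 1 + log_t + (log_t - log10 bp)_+ with random intercept and
    independent random slopes per site on both segments.  The breakpoint is
    located first, by profile likelihood of the random-intercept model over
    a grid in deg C (default: coarse 0.5 deg C scan of the central observed
    range refined to 0.1 deg C steps) -- the fixed-effect kink identifies
    the breakpoint, whereas free random slopes can absorb site
    heterogeneity and bias the search.  The full random structure is then
    fitted at the selected breakpoint, falling back to simpler structures
    if it fails to converge.
    """
    df = residuals.copy()
    n_sites = df["site_id"].nunique()
    if n_sites < min_sites:
        raise ValueError(f"need >= {min_sites} sites, got {n_sites}")
    per_site = df.groupby("site_id").size()
    if (per_site < min_years).any():
        warnings.warn("some sites have fewer than the recommended observations")
    t_c = 10.0 ** df["log_t"].to_numpy()
    lo, hi = np.quantile(t_c, [0.05, 0.95])
    if breakpoint_grid is None:
        scans = [np.arange(np.floor(lo * 2) / 2, hi + 0.25, 0.5)]
        refine = True
    else:
        scans = [np.asarray(breakpoint_grid, dtype=float)]
        refine = False
    best_bp, best_ll = None, -np.inf
    for gi, grid in enumerate(scans):
        for bp in grid:
            ll = _search_loglik(df, bp)
            if ll > best_ll:
                best_bp, best_ll = bp, ll
        if gi == 0 and refine and best_bp is not None:
            scans.append(np.arange(best_bp - 0.5, best_bp + 0.5 + 1e-9, 0.1))
    if best_bp is None:
        raise RuntimeError("no admissible breakpoint in the grid")

    res, fallback = None, None
    for structure in ("full", "slope", "intercept"):
        cand, ll = _profile_loglik(df, best_bp, structure)
        if cand is None:
            continue
        if getattr(cand, "converged", True) and np.isfinite(ll):
            res = cand
            break
        fallback = fallback or cand
    res = res or fallback
    if res is None:
        raise RuntimeError("piecewise mixed model failed on every structure")
    params = res.params
    bse = res.bse
    pre = float(params["log_t"])
    delta = float(params["t_bp"])
    se_pre = float(bse["log_t"])
    se_delta = float(bse["t_bp"])
    dof = len(df) - 3
    t_pre = pre / se_pre if se_pre > 0 else np.nan
    t_delta = delta / se_delta if se_delta > 0 else np.nan
    sd_int = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    vcomp = dict(zip(res.model.exog_vc.names, res.vcomp)) if len(res.vcomp) else {}
    sd_pre_sl = float(np.sqrt(max(vcomp.get("log_t", 0.0), 0.0)))
    sd_delta_sl = float(np.sqrt(max(vcomp.get("t_bp", 0.0), 0.0)))

    # single-line comparison model with a reduced random structure
    lrt, lrt_p = float("nan"), float("nan")
    for structure0 in (("full", "intercept") if sd_pre_sl > 0
                       else ("intercept", "full")):
        try:
            res0 = _fit_lmm(df, False, structure0)
        except Exception:
            continue
        if not (np.isfinite(res.llf) and np.isfinite(res0.llf)):
            continue
        lrt = max(0.0, 2.0 * (res.llf - res0.llf))
        # breakpoint + delta slope (+ its variance component) gained: the
        # chi2(2) reference ignores grid selection, so it is approximate
        lrt_p = float(stats.chi2.sf(lrt, 2))
        break

    return PiecewiseFit(
        breakpoint_c=float(best_bp), breakpoint_log=float(np.log10(best_bp)),
        pre_slope=pre, pre_slope_se=se_pre, pre_slope_t=float(t_pre),
        pre_slope_p=float(2 * stats.t.sf(abs(t_pre), dof)),
        post_slope=pre + delta, delta_slope=delta, delta_slope_se=se_delta,
        delta_slope_t=float(t_delta),
        delta_slope_p=float(2 * stats.t.sf(abs(t_delta), dof)),
        intercept=float(params["Intercept"]), sd_intercept=sd_int,
        sd_pre_slope=sd_pre_sl, sd_post_slope=sd_delta_sl,
        loglik=float(res.llf), lrt_stat=float(lrt), lrt_p=lrt_p,
        n=len(df), converged=bool(getattr(res, "converged", True)))
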