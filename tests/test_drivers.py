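"""Predictor construction and the bagged random-forest density models."""

import numpy as np
import pandas as pd
import pytest

from troutcap import drivers
from troutcap.drivers import (build_predictor_table, fit_density_forest,
                              partial_dependence, permutation_importance,
                              saturation_ratio, standardized_emergence_flows,
                              tune_random_forest)


class TestEmergenceFlows:
    def test_constant_at_median(self):
        days = pd.date_range("2000-03-01", "2000-04-30")
        q = pd.Series(2.0, index=days)
        q_em, q_max7d = standardized_emergence_flows(q, 2.0)
        assert q_em == pytest.approx(1.0) and q_max7d == pytest.approx(1.0)

    def test_homogeneity(self, rng):
        days = pd.date_range("2000-02-01", "2000-05-15")
        vals = rng.lognormal(0, 0.4, size=len(days))
        q = pd.Series(vals, index=days)
        a = standardized_emergence_flows(q, 1.0)
        b = standardized_emergence_flows(q * 10, 1.0)
        assert b[0] == pytest.approx(10 * a[0]) and b[1] == pytest.approx(10 * a[1])

    def test_matches_window_scan_oracle(self, rng):
        days = pd.date_range("2000-03-01", "2000-04-30")
        vals = rng.lognormal(0, 0.5, size=len(days))
        q = pd.Series(vals, index=days)
        q_em, q_max7d = standardized_emergence_flows(q, 1.3)
        assert q_em == pytest.approx(vals.mean() / 1.3)
        oracle = max(vals[i:i + 7].mean() for i in range(len(vals) - 6))
        assert q_max7d == pytest.approx(oracle / 1.3)

    def test_empty_window_rejected(self):
        q = pd.Series([1.0], index=pd.to_datetime(["2000-08-01"]))
        with pytest.raises(ValueError):
            standardized_emergence_flows(q, 1.0)


class TestSaturationRatio:
    @pytest.mark.parametrize("d,k,expected", [(5.0, 5.0, 1.0), (0.0, 5.0, 0.0),
                                              (7.5, 5.0, 1.5)])
    def test_ratio(self, d, k, expected):
        assert saturation_ratio(d, k) == expected

    def test_zero_k_flagged(self):
        assert np.isnan(saturation_ratio(1.0, 0.0))
        assert saturation_ratio(0.0, 0.0) == 0.0


def toy_tables(n_sites=2, years=(2000, 2001, 2002)):
    dens, caps, flows = [], [], []
    for s in range(n_sites):
        for j, y in enumerate(years):
            for stage, d, k in (("yoy", 100 + 10 * s + j, 200.0),
                                ("juvenile", 50 + 5 * s, 120.0 + j),
                                ("adult", 30 + s, 80.0)):
                dens.append({"site_id": f"s{s}", "year": y, "stage": stage,
                             "density": float(d)})
                caps.append({"site_id": f"s{s}", "year": y, "stage": stage,
                             "K_trout_per_ha": k})
            flows.append({"site_id": f"s{s}", "year": y, "q_em": 1.0 + 0.1 * j,
                          "q_max7d": 2.0})
    return pd.DataFrame(dens), pd.DataFrame(caps), pd.DataFrame(flows)


class TestPredictorTable:
    def test_lag_loss_and_hand_computation(self):
        dens, caps, flows = toy_tables()
        t = build_predictor_table(dens, caps, flows, "yoy")
        assert len(t) == 4  # 2 sites x (3 years - 1)
        row = t[(t.site_id == "s0") & (t.year == 2001)].iloc[0]
        # YOY: past adult D/K and K_yoy / past K_adult
        assert row["past_dk"] == pytest.approx(30 / 80)
        assert row["k_ratio"] == pytest.approx(200 / 80)
        assert row["K"] == pytest.approx(200.0)
        assert row["dk_juvenile"] == pytest.approx(50 / 121.0)
        assert row["density"] == pytest.approx(101.0)

    def test_stage_specific_lag_structure(self):
        dens, caps, flows = toy_tables()
        tj = build_predictor_table(dens, caps, flows, "juvenile")
        row = tj[(tj.site_id == "s1") & (tj.year == 2002)].iloc[0]
        assert row["past_dk"] == pytest.approx(111 / 200)  # yoy D/K at 2001
        assert row["k_ratio"] == pytest.approx(122 / 200)

    def test_missing_stage_fails_loudly(self):
        dens, caps, flows = toy_tables()
        with pytest.raises(ValueError, match="adult"):
            build_predictor_table(dens[dens.stage != "adult"], caps, flows, "yoy")

    def test_undefined_ratio_rows_dropped_and_counted(self):
        dens, caps, flows = toy_tables()
        caps.loc[(caps.site_id == "s0") & (caps.stage == "adult"),
                 "K_trout_per_ha"] = 0.0
        t = build_predictor_table(dens, caps, flows, "yoy")
        assert t.attrs["n_dropped"] == 2
        assert set(t.site_id) == {"s1"}


def synthetic_table(n=500, noise_cv=0.0, seed=5, pure_noise=False):
    rng = np.random.default_rng(seed)
    k = rng.uniform(100, 1000, size=n)
    others = {f"x{i}": rng.normal(size=n) for i in range(4)}
    y = rng.normal(size=n) if pure_noise else 2.0 * k
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        y = y * rng.lognormal(-sigma**2 / 2, sigma, size=n)
    df = pd.DataFrame({"K": k, **others, "density": y})
    df.attrs["predictors"] = ["K"] + list(others)
    df.attrs["stage"] = "test"
    return df


class TestForest:
    def test_noiseless_function_recovery(self):
        fit = fit_density_forest(synthetic_table(), mtry=3, ntree=300, seed=0)
        assert fit.oob_r2 > 0.95

    def test_pure_noise_r2_near_zero(self):
        # OOB R2 is mildly negative on pure noise (trees overfit their
        # bootstrap samples), as with R randomForest's %Var explained
        fit = fit_density_forest(synthetic_table(pure_noise=True),
                                 mtry=3, ntree=300, seed=0)
        assert -0.3 < fit.oob_r2 < 0.1

    def test_k_driven_with_cv20_noise_lands_in_regime(self):
        fit = fit_density_forest(synthetic_table(noise_cv=0.2),
                                 mtry=3, ntree=400, seed=0)
        assert 0.6 <= fit.oob_r2 <= 0.95

    def test_oob_predictions_in_scale(self):
        fit = fit_density_forest(synthetic_table(noise_cv=0.2), mtry=3,
                                 ntree=400, seed=0)
        slope = np.polyfit(fit.oob_predictions, fit.y_, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_determinism(self):
        t = synthetic_table(noise_cv=0.2)
        a = fit_density_forest(t, mtry=2, ntree=100, seed=3)
        b = fit_density_forest(t, mtry=2, ntree=100, seed=3)
        assert np.allclose(a.oob_predictions, b.oob_predictions)

    def test_agrees_with_sklearn_forest(self):
        # independent route: sklearn's own bagging/OOB machinery
        from sklearn.ensemble import RandomForestRegressor
        t = synthetic_table(noise_cv=0.2)
        fit = fit_density_forest(t, mtry=3, ntree=400, seed=0)
        sk = RandomForestRegressor(n_estimators=400, max_features=3,
                                   oob_score=True, random_state=0)
        sk.fit(t[t.attrs["predictors"]], t["density"])
        assert fit.oob_r2 == pytest.approx(sk.oob_score_, abs=0.05)

    def test_degenerate_response_rejected(self):
        t = synthetic_table()
        t["density"] = 1.0
        with pytest.raises(ValueError):
            fit_density_forest(t, mtry=2, ntree=100, seed=0)


class TestTuning:
    def test_single_candidate_grids(self):
        t = synthetic_table(n=120, noise_cv=0.2)
        assert tune_random_forest(t, [2], [100], seed=1) == (2, 100)

    def test_determinism(self):
        t = synthetic_table(n=150, noise_cv=0.3)
        a = tune_random_forest(t, [1, 3], [100, 200], seed=9)
        assert a == tune_random_forest(t, [1, 3], [100, 200], seed=9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            tune_random_forest(synthetic_table(n=10), [1], [100], seed=0)


class TestImportance:
    def test_informative_vs_null_predictors(self):
        t = synthetic_table(noise_cv=0.2)
        fit = fit_density_forest(t, mtry=2, ntree=300, seed=0)
        imp = permutation_importance(fit, seed=1)
        assert imp.index[0] == "K"
        assert all(abs(imp[x]) < 5.0 for x in ("x0", "x1", "x2", "x3"))

    def test_permuted_response_kills_importance(self):
        t = synthetic_table(noise_cv=0.2, seed=11)
        rng = np.random.default_rng(1)
        t["density"] = rng.permutation(t["density"].to_numpy())
        fit = fit_density_forest(t, mtry=2, ntree=300, seed=0)
        imp = permutation_importance(fit, seed=1)
        assert imp.abs().max() < 10.0


class TestPartialDependence:
    def test_linear_truth_slope(self):
        rng = np.random.default_rng(2)
        n = 600
        x = rng.uniform(0, 10, size=n)
        z = rng.normal(size=n)
        y = 3.0 * x + rng.normal(0, 0.5, size=n)
        df = pd.DataFrame({"x": x, "z": z, "density": y})
        df.attrs["predictors"] = ["x", "z"]
        fit = fit_density_forest(df, mtry=2, ntree=300, seed=0)
        grid = np.linspace(2, 8, 13)
        pd_curve = partial_dependence(fit, "x", grid)
        slope = np.polyfit(pd_curve["x"], pd_curve["pd"], 1)[0]
        assert slope == pytest.approx(3.0, rel=0.2)

    def test_outside_range_flat_and_flagged(self):
        t = synthetic_table(n=200, noise_cv=0.2)
        fit = fit_density_forest(t, mtry=2, ntree=100, seed=0)
        curve = partial_dependence(fit, "K", [2000.0, 3000.0])
        assert curve["extrapolated"].all()
        assert curve["pd"].iloc[0] == pytest.approx(curve["pd"].iloc[1])

    def test_unknown_predictor_rejected(self):
        fit = fit_density_forest(synthetic_table(n=100, noise_cv=0.2),
                                 mtry=2, ntree=50, seed=0)
        with pytest.raises(ValueError):
            partial_dependence(fit, "nope")
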