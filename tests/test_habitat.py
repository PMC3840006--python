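"""Physical habitat model: hydraulics, composite suitability, WUA and
intercohort segregation."""

import numpy as np
import pytest

from troutcap import habitat
from troutcap.habitat import (STAGES, SuitabilityCurve, apply_cohort_segregation,
                              build_wua_discharge_curve, composite_suitability,
                              compute_stage_wua, simulate_cell_hydraulics)

from conftest import flat_curves, make_cell, random_cells, random_curves


class TestCellHydraulics:
    def test_power_law_rating(self):
        cell = make_cell(a_d=0.5, b_d=0.4)
        assert simulate_cell_hydraulics(cell, 1.0)[0] == pytest.approx(0.5)
        assert simulate_cell_hydraulics(cell, 16.0)[0] == pytest.approx(1.5157, abs=1e-3)

    def test_zero_discharge_gives_zero_depth_and_velocity(self):
        d, v = simulate_cell_hydraulics(make_cell(), 0.0)
        assert d == 0.0 and v == 0.0

    def test_negative_discharge_rejected(self):
        with pytest.raises(ValueError):
            simulate_cell_hydraulics(make_cell(), -0.1)

    def test_monotone_in_discharge(self):
        cell = make_cell(a_d=0.3, b_d=0.35, a_v=0.6, b_v=0.25)
        qs = np.linspace(0, 5, 40)
        depths = [simulate_cell_hydraulics(cell, q)[0] for q in qs]
        assert np.all(np.diff(depths) >= 0)


class TestCompositeSuitability:
    def test_product_rule(self):
        # components 0.5 (depth), 0.8 (velocity), 1.0, 1.0 -> 0.40
        curves = {
            "depth": SuitabilityCurve("depth", "yoy", (0.0, 10.0), (0.5, 0.5)),
            "velocity": SuitabilityCurve("velocity", "yoy", (0.0, 10.0), (0.8, 0.8)),
            "substrate": SuitabilityCurve("substrate", "yoy", categories={3: 1.0}),
            "cover": SuitabilityCurve("cover", "yoy", categories={2: 1.0}),
        }
        csi = composite_suitability(make_cell(), 0.5, 0.3, curves)
        assert csi == pytest.approx(0.40)

    def test_identity_and_annihilator(self):
        full = flat_curves(1.0)["yoy"]
        assert composite_suitability(make_cell(), 1, 1, full) == 1.0
        zero = dict(full)
        zero["depth"] = SuitabilityCurve("depth", "yoy", (0.0, 10.0), (0.0, 0.0))
        assert composite_suitability(make_cell(), 1, 1, zero) == 0.0

    def test_missing_curve_is_configuration_error(self):
        curves = flat_curves(1.0)["yoy"].copy()
        del curves["cover"]
        with pytest.raises(habitat.ConfigurationError):
            composite_suitability(make_cell(), 1, 1, curves)

    def test_geometric_mean_option(self):
        curves = flat_curves(0.5)["yoy"]
        prod = composite_suitability(make_cell(), 1, 1, curves, "product")
        geo = composite_suitability(make_cell(), 1, 1, curves, "geometric_mean")
        assert prod == pytest.approx(0.5**4)
        assert geo == pytest.approx(0.5)


class TestStageWUA:
    def test_full_and_zero_suitability(self):
        cells = [make_cell("a", 600.0), make_cell("b", 400.0)]
        assert compute_stage_wua(cells, flat_curves(1.0), 1.0)["yoy"] == pytest.approx(10000.0)
        assert compute_stage_wua(cells, flat_curves(0.0), 1.0)["yoy"] == 0.0

    def test_area_weighted_sum(self):
        # two equal-area cells with CSI 0.2 and 0.6 -> 4000 m2/ha
        curves = flat_curves(1.0)
        for stage in STAGES:
            curves[stage]["substrate"] = SuitabilityCurve(
                "substrate", stage, categories={1: 0.2, 2: 0.6})
        cells = [make_cell("a", 5000.0, substrate=1),
                 make_cell("b", 5000.0, substrate=2)]
        wua = compute_stage_wua(cells, curves, 1.0, segregation=False)
        assert wua["adult"] == pytest.approx(4000.0)

    def test_agrees_with_brute_force_loop(self, rng):
        cells = random_cells(rng)
        curves = random_curves(rng)
        q = 1.7
        got = compute_stage_wua(cells, curves, q, segregation=False)
        total = sum(c.area for c in cells)
        for stage in STAGES:
            acc = 0.0
            for c in cells:
                d, v = c.a_d * q**c.b_d, c.a_v * q**c.b_v
                csi = (np.interp(d, curves[stage]["depth"].x,
                                 curves[stage]["depth"].suitability)
                       * np.interp(v, curves[stage]["velocity"].x,
                                   curves[stage]["velocity"].suitability)
                       * curves[stage]["substrate"].categories[c.substrate]
                       * curves[stage]["cover"].categories[c.cover])
                acc += csi * c.area
            assert got[stage] == pytest.approx(acc / total * 1e4, rel=1e-9)

    def test_removing_a_cell_never_increases_wua(self, rng):
        cells = random_cells(rng, n=20)
        curves = random_curves(rng)
        site_area = sum(c.area for c in cells)
        base = compute_stage_wua(cells, curves, 1.0, site_area_m2=site_area)
        for drop in (0, 7, 19):
            sub = [c for i, c in enumerate(cells) if i != drop]
            less = compute_stage_wua(sub, curves, 1.0, site_area_m2=site_area)
            for stage in STAGES:
                assert less[stage] <= base[stage] + 1e-9


class TestSegregation:
    def test_dominated_cell_excluded_from_yoy(self):
        csi = {"yoy": [0.5], "juvenile": [0.0], "adult": [0.9]}
        adj = apply_cohort_segregation(csi)
        assert adj["yoy"][0] == 0.0
        assert adj["adult"][0] == 0.9

    def test_tie_leaves_cell_shared(self):
        csi = {"yoy": [0.5], "juvenile": [0.2], "adult": [0.5]}
        adj = apply_cohort_segregation(csi)
        assert adj["yoy"][0] == 0.5

    def test_no_overlap_leaves_wua_unchanged(self):
        csi = {"yoy": [0.5, 0.0], "juvenile": [0.0, 0.3], "adult": [0.0, 0.9]}
        adj = apply_cohort_segregation(csi)
        assert list(adj["yoy"]) == [0.5, 0.0]

    def test_adjusted_bounded_by_raw_and_adult_invariant(self, rng):
        cells = random_cells(rng, n=30)
        curves = random_curves(rng)
        for q in (0.3, 1.0, 3.0):
            raw = compute_stage_wua(cells, curves, q, segregation=False)
            adj = compute_stage_wua(cells, curves, q, segregation=True)
            for stage in STAGES:
                assert 0.0 <= adj[stage] <= raw[stage] + 1e-9 <= 10_000 + 1e-6
            assert adj["adult"] == pytest.approx(raw["adult"])


class TestWUACurve:
    def test_single_point_grid_is_constant(self):
        cells = [make_cell()]
        curves = build_wua_discharge_curve(cells, flat_curves(0.7), [1.0])
        assert curves["yoy"](0.1) == curves["yoy"](1.0) == curves["yoy"](10.0)

    def test_grid_point_returned_exactly(self, rng):
        cells = random_cells(rng, n=10)
        hsc = random_curves(rng)
        grid = [0.2, 0.8, 1.5, 3.0]
        curves = build_wua_discharge_curve(cells, hsc, grid)
        direct = compute_stage_wua(cells, hsc, 0.8)
        assert curves["adult"](0.8) == pytest.approx(direct["adult"])

    def test_interpolation_matches_dense_grid_for_monotone_model(self):
        # increasing depth suitability + monotone ratings -> WUA non-decreasing
        curves = flat_curves(1.0)
        for stage in STAGES:
            curves[stage]["depth"] = SuitabilityCurve(
                "depth", stage, (0.0, 2.0), (0.0, 1.0))
        cells = [make_cell("a", 100.0, a_d=0.4, b_d=0.4)]
        out = build_wua_discharge_curve(cells, curves, np.linspace(0.1, 5, 12))
        assert np.all(np.diff(out["yoy"].wua) >= -1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_wua_discharge_curve([make_cell()], flat_curves(1.0), [])
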