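"""Cell-based physical habitat model producing stage-specific WUA–discharge curves.

A study site is a mosaic of cells, each with a fixed area, channel structure
(substrate and cover codes) and hydraulics given by per-cell power-law rating
curves (depth and velocity as functions of discharge).  Habitat quality is
scored against stage-specific habitat selection curves and aggregated to a
composite suitability index (CSI) per cell; the area-weighted sum of CSI,
expressed per hectare of wetted site area, is the weighted usable area (WUA).

Spatial segregation of cohorts is modelled by removing from a younger stage's
WUA every cell in which an older stage (dominance order adult > juvenile >
young-of-the-year) attains a strictly higher CSI: younger fish do not hold
cells where they are dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAGES = ("yoy", "juvenile", "adult")
#: older stages dominate younger ones in shared cells
DOMINANCE = {"yoy": ("juvenile", "adult"), "juvenile": ("adult",), "adult": ()}

HECTARE_M2 = 10_000.0


class ConfigurationError(ValueError):
    """A required suitability curve or model input is missing."""


@dataclass(frozen=True)
class StreamCell:
    """One hydraulic/structural cell of a study site.

    Depth and velocity follow power-law rating curves d = a_d * Q**b_d and
    v = a_v * Q**b_v (SI units; Q in m3/s).
    """

    cell_id: str
    area: float  # m2
    substrate: int
    cover: int
    a_d: float
    b_d: float
    a_v: float
    b_v: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"cell {self.cell_id}: area must be > 0")
        if self.a_d < 0 or self.a_v < 0:
            raise ValueError(f"cell {self.cell_id}: rating coefficients a must be >= 0")
        for b in (self.b_d, self.b_v):
            if not np.isfinite(b):
                raise ValueError(f"cell {self.cell_id}: rating exponent not finite")


@dataclass(frozen=True)
class SuitabilityCurve:
    """Habitat selection curve for one variable, stage and reach type.

    Continuous variables (depth, velocity) interpolate piecewise-linearly
    between ``x`` breakpoints, clamping outside the observed range.
    Categorical variables (substrate, cover) map codes to suitabilities.
    """

    variable: str  # depth | velocity | substrate | cover
    stage: str
    x: tuple = ()
    suitability: tuple = ()
    categories: dict | None = None
    reach_type: str = "default"

    def __post_init__(self) -> None:
        if self.variable in ("depth", "velocity"):
            vals = np.asarray(self.suitability, dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError("suitability values must lie in [0, 1]")
            if len(self.x) != len(vals) or len(vals) < 1:
                raise ValueError("breakpoints and suitabilities must align")
        else:
            if not self.categories:
                raise ValueError(f"categorical curve {self.variable} needs categories")
            if any(not 0 <= v <= 1 for v in self.categories.values()):
                raise ValueError("suitability values must lie in [0, 1]")

    def evaluate(self, value) -> float:
        if self.categories is not None:
            try:
                return float(self.categories[value])
            except KeyError:
                raise ConfigurationError(
                    f"{self.variable} code {value!r} not in curve for stage {self.stage}"
                ) from None
        return float(np.interp(value, self.x, self.suitability))


@dataclass(frozen=True)
class StageWUACurve:
    """WUA (m2 per ha of site) as a function of discharge for one stage."""

    stage: str
    q: np.ndarray
    wua: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        wua = np.asarray(self.wua, dtype=float)
        if q.size == 0:
            raise ValueError("empty discharge grid")
        if q.size > 1 and not np.all(np.diff(q) > 0):
            raise ValueError("discharge grid must be strictly increasing")
        if np.any(wua < -1e-9) or np.any(wua > HECTARE_M2 + 1e-9):
            raise ValueError("WUA must lie in [0, 10000] m2/ha")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "wua", wua)

    def __call__(self, q):
        """Evaluate by linear interpolation; clamp outside the grid."""
        return np.interp(q, self.q, self.wua)


def simulate_cell_hydraulics(cell: StreamCell, q: float) -> tuple[float, float]:
    """Depth (m) and velocity (m/s) in a cell at discharge ``q`` (m3/s)."""
    if q < 0:
        raise ValueError("discharge must be >= 0")
    return cell.a_d * q**cell.b_d, cell.a_v * q**cell.b_v


def _component_suitabilities(cell: StreamCell, depth, velocity, curves: dict) -> list[float]:
    values = {"depth": depth, "velocity": velocity,
              "substrate": cell.substrate, "cover": cell.cover}
    out = []
    for var in ("depth", "velocity", "substrate", "cover"):
        if var not in curves:
            raise ConfigurationError(f"missing suitability curve for {var!r}")
        out.append(curves[var].evaluate(values[var]))
    return out


def composite_suitability(cell: StreamCell, depth: float, velocity: float,
                          curves: dict, aggregation: str = "product") -> float:
    """Composite suitability index in [0, 1] for one cell and stage.

    ``curves`` maps variable name -> SuitabilityCurve for a single stage.
    ``aggregation`` is "product" (PHABSIM convention, default) or
    "geometric_mean".
    """
    comps = _component_suitabilities(cell, depth, velocity, curves)
    prod = float(np.prod(comps))
    if aggregation == "product":
        return prod
    if aggregation == "geometric_mean":
        return prod ** (1.0 / len(comps))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _csi_matrix(cells, curves_by_stage, q, aggregation):
    """CSI per (cell, stage) at discharge q, as dict stage -> array."""
    csi = {}
    for stage in STAGES:
        if stage not in curves_by_stage:
            raise ConfigurationError(f"missing curves for stage {stage!r}")
        vals = np.empty(len(cells))
        for j, cell in enumerate(cells):
            d, v = simulate_cell_hydraulics(cell, q)
            vals[j] = composite_suitability(cell, d, v, curves_by_stage[stage],
                                            aggregation)
        csi[stage] = vals
    return csi


def apply_cohort_segregation(csi_by_stage: dict) -> dict:
    """Zero out a younger stage's CSI in cells where an older stage dominates.

    A cell is excluded from a younger stage when any older stage has strictly
    greater CSI there (ties leave the cell shared; a dominating stage must
    itself have CSI > 0, which strict inequality over a non-negative CSI
    guarantees).  Adult CSI is never modified.
    """
    adjusted = {}
    for stage in STAGES:
        vals = np.array(csi_by_stage[stage], dtype=float, copy=True)
        for older in DOMINANCE[stage]:
            dominated = np.asarray(csi_by_stage[older]) > vals
            vals[dominated] = 0.0
        adjusted[stage] = vals
    return adjusted


def compute_stage_wua(cells, curves_by_stage: dict, q: float, *,
                      site_area_m2: float | None = None,
                      aggregation: str = "product",
                      segregation: bool = True) -> dict:
    """Stage -> WUA (m2 per ha of site area) at a single discharge.

    WUA(stage) = sum_cells CSI(cell, stage) * area(cell), normalised per
    hectare of site area (total cell area unless ``site_area_m2`` given).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("no cells supplied")
    areas = np.array([c.area for c in cells])
    total = site_area_m2 if site_area_m2 is not None else float(areas.sum())
    if total <= 0:
        raise ValueError("site area must be > 0")
    csi = _csi_matrix(cells, curves_by_stage, q, aggregation)
    if segregation:
        csi = apply_cohort_segregation(csi)
    return {stage: float((csi[stage] * areas).sum()) / total * HECTARE_M2
            for stage in STAGES}


def build_wua_discharge_curve(cells, curves_by_stage: dict, q_grid, *,
                              site_area_m2: float | None = None,
                              aggregation: str = "product",
                              segregation: bool = True) -> dict:
    """Evaluate the full habitat model on a discharge grid.

    Returns stage -> StageWUACurve; queries between grid points interpolate
    linearly and queries outside the grid clamp to the nearest endpoint.
    """
    q_grid = np.sort(np.unique(np.asarray(q_grid, dtype=float)))
    if q_grid.size == 0:
        raise ValueError("empty discharge grid")
    wua = {stage: np.empty(q_grid.size) for stage in STAGES}
    for i, q in enumerate(q_grid):
        at_q = compute_stage_wua(cells, curves_by_stage, q,
                                 site_area_m2=site_area_m2,
                                 aggregation=aggregation,
                                 segregation=segregation)
        for stage in STAGES:
            wua[stage][i] = at_q[stage]
    return {stage: StageWUACurve(stage, q_grid, wua[stage]) for stage in STAGES}
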