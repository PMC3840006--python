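import numpy as np
import pytest

from troutcap.habitat import STAGES, StreamCell, SuitabilityCurve


def make_cell(cell_id="c0", area=10.0, substrate=3, cover=2,
              a_d=0.5, b_d=0.4, a_v=0.5, b_v=0.3) -> StreamCell:
    return StreamCell(cell_id, area, substrate, cover, a_d, b_d, a_v, b_v)


def flat_curves(value=1.0):
    """Suitability curves that score every condition the same."""
    out = {}
    for stage in STAGES:
        out[stage] = {
            "depth": SuitabilityCurve("depth", stage, (0.0, 10.0), (value, value)),
            "velocity": SuitabilityCurve("velocity", stage, (0.0, 10.0),
                                         (value, value)),
            "substrate": SuitabilityCurve("substrate", stage,
                                          categories={i: value for i in range(1, 9)}),
            "cover": SuitabilityCurve("cover", stage,
                                      categories={i: value for i in range(0, 5)}),
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_cells(rng, n=50):
    return [make_cell(f"c{i}", area=float(rng.uniform(1, 30)),
                      substrate=int(rng.integers(1, 7)),
                      cover=int(rng.integers(0, 4)),
                      a_d=float(rng.uniform(0.05, 0.7)),
                      b_d=float(rng.uniform(0.2, 0.5)),
                      a_v=float(rng.uniform(0.05, 0.8)),
                      b_v=float(rng.uniform(0.2, 0.5)))
            for i in range(n)]


def random_curves(rng):
    """Unimodal random suitability curves per stage."""
    out = {}
    for stage in STAGES:
        x = np.sort(rng.uniform(0, 2.0, size=5))
        peak = rng.uniform(0.5, 1.0)
        s = (0.0, rng.uniform(0, peak), peak, rng.uniform(0, peak), 0.0)
        xv = np.sort(rng.uniform(0, 2.0, size=5))
        pv = rng.uniform(0.5, 1.0)
        sv = (0.1, rng.uniform(0.1, pv), pv, rng.uniform(0, pv), 0.0)
        out[stage] = {
            "depth": SuitabilityCurve("depth", stage, tuple(x), s),
            "velocity": SuitabilityCurve("velocity", stage, tuple(xv), sv),
            "substrate": SuitabilityCurve(
                "substrate", stage,
                categories={i: float(rng.uniform(0.2, 1)) for i in range(1, 7)}),
            "cover": SuitabilityCurve(
                "cover", stage,
                categories={i: float(rng.uniform(0.2, 1)) for i in range(0, 4)}),
        }
    return out
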