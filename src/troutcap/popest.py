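"""Abundance and density from three-pass removal (depletion) electrofishing.

Under the constant-effort removal model, each pass captures a binomial
fraction p of the fish remaining, so expected catches decline geometrically:
E[c_i] = N * p * q**(i-1) with q = 1 - p.  The estimator is the classical
three-removal maximum-likelihood solution: the catch pattern, conditional
on the total catch T = c1+c2+c3, is multinomial with pass probabilities
proportional to p*q**(i-1); maximizing that conditional likelihood reduces
to one monotone equation in q,

    R / T = q/(1-q) - k*q**k/(1-q**k),   k = 3,

with R = c2 + 2*c3 the number of prior passes summed over catches, and the
abundance follows by expanding the total catch by the overall capture
probability, N_hat = T / (1 - q_hat**k).  On an exactly geometric catch
series (e.g. 100, 50, 25) this recovers the generating (N, p) exactly.  A
valid estimate requires a declining pattern, R < T (equivalently c1 > c3).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy.optimize import brentq

K_PASSES = 3


class NoEstimateError(ValueError):
    """The removal MLE does not exist for this catch pattern."""


@dataclass(frozen=True)
class RemovalSample:
    site_id: str
    year: int
    stage: str
    c1: int
    c2: int
    c3: int
    site_area_ha: float

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("catches must be non-negative")
        if self.site_area_ha <= 0:
            raise ValueError("site area must be > 0 ha")


@dataclass(frozen=True)
class DensityRecord:
    site_id: str
    year: int
    stage: str
    density: float       # trout/ha
    density_var: float
    p_hat: float


def _profile_equation(q: float, k: int = K_PASSES) -> float:
    return q / (1.0 - q) - k * q**k / (1.0 - q**k)


def conditional_loglik(q: float, catches) -> float:
    """Log-likelihood of the catch split conditional on the total catch.

    Pass i has conditional probability p*q**(i-1) / (1 - q**k).  This is
    the objective the three-removal estimator maximizes; exposed so tests
    can check the solution against a brute-force grid in q.
    """
    if not 0 < q < 1:
        return -np.inf
    p = 1.0 - q
    total = sum(catches)
    cap = 1.0 - q**K_PASSES
    ll = -total * np.log(cap)
    for i, c in enumerate(catches):
        if c > 0:
            ll += c * (np.log(p) + i * np.log(q))
    return float(ll)


def removal_loglik(n: float, p: float, catches) -> float:
    """Unconditional constant-p removal log-likelihood (multinomial over
    passes and the never-caught remainder); kept for reference checks."""
    catches = np.asarray(catches)
    total = int(catches.sum())
    if n < total or not 0 < p <= 1:
        return -np.inf
    q = 1.0 - p
    ll = lgamma(n + 1) - lgamma(n - total + 1) - sum(lgamma(c + 1) for c in catches)
    for i, c in enumerate(catches):
        if c > 0:
            if q == 0 and i > 0:
                return -np.inf
            ll += c * np.log(p) + (c * i * np.log(q) if i > 0 else 0.0)
    if n > total:
        if q == 0:
            return -np.inf
        ll += (n - total) * K_PASSES * np.log(q)
    return float(ll)


def _variance(n_hat: float, p_hat: float) -> float:
    """Standard large-sample variance of the removal abundance estimator."""
    q = 1.0 - p_hat
    cap = 1.0 - q**K_PASSES  # overall capture probability over k passes
    denom = cap**2 - (K_PASSES * p_hat) ** 2 * q ** (K_PASSES - 1)
    if denom <= 0:
        return float("inf")
    return n_hat * cap * q**K_PASSES / denom


def zippin_seber_estimate(c1: int, c2: int, c3: int) -> tuple[float, float, float]:
    """(N_hat, p_hat, var_N) for a three-pass removal sample.

    Solved numerically in q = 1 - p on the monotone profile equation (see
    module docstring); N_hat is continuous (no rounding).  Raises
    NoEstimateError when catches do not decline enough for the MLE to exist
    (c1 <= c3).  A zero total catch returns (0, nan, 0).
    """
    if min(c1, c2, c3) < 0:
        raise ValueError("catches must be non-negative")
    total = c1 + c2 + c3
    if total == 0:
        return 0.0, float("nan"), 0.0
    r_stat = c2 + 2 * c3
    if r_stat == 0:
        # all fish taken on the first pass: boundary MLE p = 1
        return float(total), 1.0, 0.0
    if c1 <= c3:
        raise NoEstimateError(
            f"non-declining catches ({c1}, {c2}, {c3}): removal MLE undefined")
    ratio = r_stat / total
    q_hat = brentq(lambda q: _profile_equation(q) - ratio, 1e-12, 1.0 - 1e-12)
    p_hat = 1.0 - q_hat
    n_hat = total / (1.0 - q_hat**K_PASSES)
    return float(n_hat), float(p_hat), float(_variance(n_hat, p_hat))


def density_estimate(sample: RemovalSample) -> DensityRecord:
    """Convert a removal sample to density (trout/ha) with delta-method variance."""
    n_hat, p_hat, var_n = zippin_seber_estimate(sample.c1, sample.c2, sample.c3)
    a = sample.site_area_ha
    return DensityRecord(sample.site_id, sample.year, sample.stage,
                         n_hat / a, var_n / a**2, p_hat)
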