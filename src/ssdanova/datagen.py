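"""Tukey g-and-h simulation of normal and non-normal group data.

The g-and-h family transforms a standard normal X into

    T(X) = A + B * exp(h X^2 / 2) * (exp(g X) - 1) / g        (g != 0)
    T(X) = A + B * exp(h X^2 / 2) * X                         (g  = 0)

with g steering skewness, h tail weight, A location and B scale.  Raw
moments of the base variate Y = T(X) with A=0, B=1 have the closed form

    E[Y^n] = g^-n * sum_i (-1)^i C(n,i) exp(((n-i) g)^2 / (2 (1 - n h)))
             / sqrt(1 - n h),          valid for h < 1/n,

which moment matching uses: (g, h) are solved from target skewness and
excess kurtosis, then (A, B) calibrated so the population mean and variance
of T(X) equal the requested group mean and variance.  Matching the fourth
moment requires h < 1/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .populations import PopulationSpec

__all__ = ["GandHParams", "solve_g_and_h", "calibrate_AB", "gh_transform", "simulate_dataset"]

_H_MAX = 0.25 - 1e-9


class FeasibilityError(ValueError):
    """Target (skewness, kurtosis) outside the reachable g-and-h region."""


@dataclass(frozen=True)
class GandHParams:
    g: float
    h: float
    A: float
    B: float

    def __post_init__(self):
        if self.h >= 0.25:
            raise ValueError("h must be below 1/4 for the fourth moment to exist")
        if self.B <= 0:
            raise ValueError("scale B must be positive")


def _raw_moments(g: float, h: float, n_max: int = 4) -> np.ndarray:
    """Raw moments E[Y^n], n = 1..n_max, of the base (A=0, B=1) variate."""
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        if n * h >= 1:
            raise ValueError(f"moment {n} does not exist for h={h}")
        c = 1.0 - n * h
        if abs(g) < 1e-10:
            # symmetric h-distribution: odd moments 0, even E[X^n e^{n h X^2/2}]
            out[n - 1] = 0.0 if n % 2 else _double_factorial(n - 1) / c ** ((n + 1) / 2)
        else:
            i = np.arange(n + 1)
            terms = (-1.0) ** i * _binom(n, i) * np.exp(((n - i) * g) ** 2 / (2 * c))
            out[n - 1] = terms.sum() / (g**n * math.sqrt(c))
    return out


def _binom(n, i):
    return np.array([math.comb(n, int(j)) for j in np.atleast_1d(i)], dtype=float)


def _double_factorial(n: int) -> float:
    return float(np.prod(np.arange(n, 0, -2))) if n > 0 else 1.0


def gh_skew_kurt(g: float, h: float) -> tuple[float, float]:
    """Standardized skewness and excess kurtosis of the g-and-h variate."""
    m1, m2, m3, m4 = _raw_moments(g, h)
    var = m2 - m1**2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    return mu3 / var**1.5, mu4 / var**2 - 3.0


def solve_g_and_h(skewness: float, excess_kurtosis: float) -> tuple[float, float]:
    """(g, h) whose g-and-h variate matches the target shape to 1e-8.

    Feasibility requires excess_kurtosis >= skewness^2 - 2 and, for the
    moment-based solve, an attainable target with h < 1/4.  (0, 0) is
    returned exactly for a normal target.
    """
    if excess_kurtosis < skewness**2 - 2:
        raise FeasibilityError(
            f"targets (skew={skewness}, excess kurtosis={excess_kurtosis}) violate "
            "kurtosis >= skewness^2 - 2"
        )
    if skewness == 0 and excess_kurtosis == 0:
        return 0.0, 0.0

    if skewness == 0:
        # symmetric: excess kurtosis 3(1-2h)^3/(1-4h)^(5/2) - 3, increasing on
        # h >= 0 (to +inf as h -> 1/4) and attaining a minimum of about -1.55
        # near h = -1 on the lighter-tailed side
        def kurt_gap(h):
            return gh_skew_kurt(0.0, h)[1] - excess_kurtosis

        if excess_kurtosis > 0:
            h = optimize.brentq(kurt_gap, 0.0, _H_MAX, xtol=1e-14)
        else:
            hmin = optimize.minimize_scalar(
                lambda h: gh_skew_kurt(0.0, h)[1], bounds=(-5.0, 0.0), method="bounded"
            ).x
            if kurt_gap(hmin) > 0:
                raise FeasibilityError(
                    f"excess kurtosis {excess_kurtosis} unreachable with g=0 "
                    f"(symmetric g-and-h floor is {gh_skew_kurt(0.0, hmin)[1]:.3f})"
                )
            h = optimize.brentq(kurt_gap, hmin, 0.0, xtol=1e-14)
        return 0.0, float(h)

    sign = 1.0 if skewness > 0 else -1.0

    def residual(params):
        g, h = params
        try:
            s, k = gh_skew_kurt(g, h)
        except (ValueError, OverflowError, FloatingPointError):
            return [1e6, 1e6]
        if not (np.isfinite(s) and np.isfinite(k)):
            return [1e6, 1e6]
        return [s - skewness, k - excess_kurtosis]

    # keep |g| away from 0, where the alternating-sum moment formula cancels
    g_lo, g_hi = (0.001, 5.0) if sign > 0 else (-5.0, -0.001)
    best = None
    for g0, h0 in ((0.1, 0.01), (0.5, 0.05), (1.0, 0.1), (0.2, -0.05), (0.05, 0.2)):
        sol = optimize.least_squares(
            residual,
            x0=[np.clip(sign * g0, g_lo, g_hi), h0],
            bounds=([g_lo, -20.0], [g_hi, _H_MAX]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-18:
            break
    g, h = best.x
    res = residual((g, h))
    if max(abs(res[0]), abs(res[1])) > 1e-8:
        raise FeasibilityError(
            f"no g-and-h solution with h < 1/4 for (skew={skewness}, "
            f"excess kurtosis={excess_kurtosis}); residuals {res}"
        )
    return float(g), float(h)


def calibrate_AB(g: float, h: float, target_mean: float, target_variance: float) -> GandHParams:
    """Location A and scale B so that T(X) has the requested mean and variance."""
    if h >= 0.5:
        raise ValueError("variance does not exist for h >= 1/2")
    if target_variance <= 0:
        raise ValueError("target variance must be positive")
    if g == 0 and h == 0:
        return GandHParams(0.0, 0.0, float(target_mean), math.sqrt(target_variance))
    m1, m2 = _raw_moments(g, h, n_max=2)
    base_var = m2 - m1**2
    B = math.sqrt(target_variance / base_var)
    A = target_mean - B * m1
    return GandHParams(float(g), float(h), A, B)


def gh_transform(x: np.ndarray, params: GandHParams) -> np.ndarray:
    """Apply the g-and-h transform elementwise to standard normal draws."""
    x = np.asarray(x, dtype=float)
    tail = np.exp(0.5 * params.h * x * x)
    if params.g == 0:
        core = x
    else:
        core = np.expm1(params.g * x) / params.g
    return params.A + params.B * tail * core


def population_params(pop: PopulationSpec) -> list[GandHParams]:
    """Calibrated g-and-h parameters for each group of a population."""
    out = []
    for m, v, s, e in zip(pop.means, pop.variances, pop.skewness, pop.excess_kurtosis):
        g, h = solve_g_and_h(s, e)
        out.append(calibrate_AB(g, h, m, v))
    return out


def simulate_dataset(pop: PopulationSpec, N: int, rng: np.random.Generator) -> np.ndarray:
    """One (N, K) dataset from the population; identity transform when normal."""
    if N < 2:
        raise ValueError("need N >= 2 per group")
    x = rng.standard_normal((N, pop.K))
    if pop.is_normal:
        means = np.asarray(pop.means)
        sds = np.sqrt(np.asarray(pop.variances))
        return means + sds * x
    params = population_params(pop)
    cols = [gh_transform(x[:, k], p) for k, p in enumerate(params)]
    return np.column_stack(cols)
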