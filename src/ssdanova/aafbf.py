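"""Approximate adjusted fractional Bayes factors for constrained hypotheses.

The Bayes factor of a constrained hypothesis H_z against the unconstrained
alternative H_a is BF_za = f_z / c_z, where the fit f_z is the share of a
normal approximation to the posterior of the K group means in agreement with
H_z, and the complexity c_z is the same share of a fractional prior.  The
posterior approximation is N(centers, diag(s_k^2/N)); the prior is centred
at the origin with variances inflated by 1/b, where b = J/(K*N) spends the
information of J/K observations per group (J = number of independent
constraints; 2J and 3J variants probe prior sensitivity).

Hypotheses with equality constraints are evaluated as the multivariate
normal density of the equality contrasts at zero times the probability of
the inequality region conditioned on the equalities; inequality regions of
dimension one or two use closed-form normal CDFs (via Owen's T function for
the bivariate case), higher dimensions quasi-random Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .estimators import GroupSummaries
from .hypotheses import ComparisonPair, Hypothesis

__all__ = [
    "NormalApprox",
    "FitComplexity",
    "BayesFactorResult",
    "fraction_b",
    "format_b",
    "approximate_distributions",
    "fit_or_complexity",
    "bayes_factor",
]


@dataclass(frozen=True)
class NormalApprox:
    """A diagonal-covariance normal distribution over the K group means."""

    mean: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if m.shape != v.shape or m.ndim != 1:
            raise ValueError("mean and variances must be equal-length vectors")
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "variances", v)


@dataclass(frozen=True)
class FitComplexity:
    """Fit or complexity of one hypothesis under one distribution.

    ``density_part`` is the multivariate normal density of the equality
    contrasts at zero (1 when there are none); ``probability_part`` the
    probability of the inequality region, conditioned on the equalities when
    both are present (1 when there are none); ``value`` their product.
    ``mc_se`` is a Monte-Carlo standard error when sampling was used.
    """

    density_part: float
    probability_part: float
    mc_se: float = 0.0

    @property
    def value(self) -> float:
        return self.density_part * self.probability_part


@dataclass(frozen=True)
class BayesFactorResult:
    bf_12: float
    bf_21: float
    fit1: FitComplexity
    comp1: FitComplexity
    fit2: FitComplexity
    comp2: FitComplexity
    b_used: float
    infinite: bool = False


def fraction_b(J: int, K: int, N: int, multiplier: int = 1) -> float:
    """Prior fraction b = multiplier * J / (K * N) per group."""
    if J < 1 or K < 1 or N < 1 or multiplier < 1:
        raise ValueError("J, K, N and multiplier must be positive")
    b = multiplier * J / (K * N)
    if b > 1:
        raise ValueError(f"prior fraction b={b:.3g} exceeds 1 (more prior than data)")
    return b


def format_b(b: float) -> str:
    """b truncated (floored) to three decimals, as reported (0.01754 -> '0.017')."""
    return f"{math.floor(b * 1000) / 1000:.3f}"


def approximate_distributions(
    summaries: GroupSummaries, b: float
) -> tuple[NormalApprox, NormalApprox]:
    """Normal posterior and fractional prior for a set of group summaries."""
    if not 0 < b <= 1:
        raise ValueError("b must lie in (0, 1]")
    obsvar = np.asarray(summaries.obs_variances, dtype=float)
    posterior = NormalApprox(np.asarray(summaries.centers, dtype=float), obsvar / summaries.N)
    prior = NormalApprox(np.zeros(summaries.K), obsvar / (b * summaries.N))
    return posterior, prior


# --- bivariate normal CDF, vectorized ------------------------------------


def _owens_t_term(h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Owen's T(h, a) allowing a = +-inf, where T(h, +-inf) = +-Phi(-|h|)/2."""
    finite = np.isfinite(a)
    out = np.where(
        finite,
        special.owens_t(h, np.where(finite, a, 0.0)),
        np.sign(a) * 0.5 * stats.norm.cdf(-np.abs(h)),
    )
    return out


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized, exact up to Owen's T accuracy; handles h or k equal to zero
    (the constant case for prior complexities, whose mean is the origin).
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_h = np.where(h != 0, (k - rho * h) / (h * s), np.sign(k - rho * h) * np.inf)
        a_k = np.where(k != 0, (h - rho * k) / (k * s), np.sign(h - rho * k) * np.inf)
    delta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - _owens_t_term(h, a_h)
        - _owens_t_term(k, a_k)
        - delta
    )
    both_zero = (h == 0) & (k == 0)
    val = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), val)
    return np.clip(val, 0.0, 1.0)


# --- batched fit/complexity on (T, K) parameter stacks --------------------


def _mvn_density_at_zero(mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Density of N(mean, cov) at the origin; batched over leading axis."""
    p = mean.shape[-1]
    sign, logdet = np.linalg.slogdet(cov)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("singular equality-contrast covariance (redundant rows?)")
    sol = np.linalg.solve(cov, mean[..., None])[..., 0]
    quad = np.einsum("...p,...p->...", mean, sol)
    return np.exp(-0.5 * (quad + logdet + p * math.log(2 * math.pi)))


def _contrast_moments(R: np.ndarray, mean: np.ndarray, variances: np.ndarray):
    """Mean and covariance of R @ mu for mu ~ N(mean, diag(variances)), batched."""
    m = mean @ R.T
    cov = np.einsum("pk,...k,qk->...pq", R, variances, R)
    return m, cov


def fit_complexity_batch(
    h: Hypothesis, mean: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(density_part, probability_part), batched over leading axes of mean/variances.

    Exact throughout for at most two inequality rows (after conditioning on
    any equality rows); three or more inequality rows fall back to numerical
    integration per element.
    """
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    T = mean.shape[0]
    dens = np.ones(T)
    prob = np.ones(T)
    RE = h.equality_matrix() if h.has_equalities else None
    RI = h.inequality_matrix() if h.has_inequalities else None

    if RE is not None:
        m_E, cov_E = _contrast_moments(RE, mean, variances)
        dens = _mvn_density_at_zero(m_E, cov_E)

    if RI is not None:
        m_I, cov_I = _contrast_moments(RI, mean, variances)
        if RE is not None:
            # condition the inequality contrasts on the equality contrasts = 0
            m_E, cov_E = _contrast_moments(RE, mean, variances)
            cov_IE = np.einsum("pk,...k,qk->...pq", RI, variances, RE)
            gain = np.linalg.solve(cov_E, np.swapaxes(cov_IE, -1, -2))  # (T, p_E, q_I)
            m_I = m_I - np.einsum("...pq,...p->...q", gain, m_E)
            cov_I = cov_I - cov_IE @ gain
        sd = np.sqrt(np.einsum("...pp->...p", cov_I))
        z = m_I / sd
        q = RI.shape[0]
        if q == 1:
            prob = stats.norm.cdf(z[..., 0])
        elif q == 2:
            rho = cov_I[..., 0, 1] / (sd[..., 0] * sd[..., 1])
            prob = np.asarray(bvn_cdf(z[..., 0], z[..., 1], rho))
        else:
            prob = np.empty(T)
            for t in range(T):
                prob[t] = stats.multivariate_normal.cdf(
                    m_I[t], mean=np.zeros(q), cov=cov_I[t], allow_singular=True
                )
        prob = np.atleast_1d(prob)
    return dens, prob


def fit_or_complexity(
    h: Hypothesis,
    dist: NormalApprox,
    mc_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> FitComplexity:
    """Fit (posterior) or complexity (prior) of one constrained hypothesis.

    Exact for up to two inequality rows; otherwise the inequality-region
    probability is estimated by quasi-random (Sobol) Monte Carlo on the
    (conditioned) contrast distribution, with a binomial-style standard
    error reported.
    """
    if h.kind == "unconstrained_Ha":
        return FitComplexity(1.0, 1.0)
    if h.kind == "complement_Hc":
        raise ValueError("Hc is evaluated through its paired hypothesis in bayes_factor")
    n_ineq = len(h.inequality_rows)
    if n_ineq <= 2:
        dens, prob = fit_complexity_batch(h, dist.mean[None], dist.variances[None])
        return FitComplexity(float(dens[0]), float(prob[0]))
    dens = 1.0
    if h.has_equalities:
        RE = h.equality_matrix()
        m_E, cov_E = _contrast_moments(RE, dist.mean[None], dist.variances[None])
        dens = float(_mvn_density_at_zero(m_E, cov_E)[0])
    m, cov = _conditioned_inequality_moments(h, dist)
    sampler = stats.qmc.Sobol(d=m.size, scramble=True, rng=rng)
    u = sampler.random(mc_draws)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = stats.norm.ppf(u)
    L = np.linalg.cholesky(cov)
    draws = m + z @ L.T
    hits = np.all(draws > 0, axis=1)
    p = float(hits.mean())
    se = math.sqrt(max(p * (1 - p), 1e-300) / mc_draws)
    return FitComplexity(dens, p, mc_se=se)


def _conditioned_inequality_moments(h: Hypothesis, dist: NormalApprox):
    RI = h.inequality_matrix()
    m_I, cov_I = _contrast_moments(RI, dist.mean[None], dist.variances[None])
    if h.has_equalities:
        RE = h.equality_matrix()
        m_E, cov_E = _contrast_moments(RE, dist.mean[None], dist.variances[None])
        cov_IE = np.einsum("pk,k,qk->pq", RI, dist.variances, RE)[None]
        gain = np.linalg.solve(cov_E, np.swapaxes(cov_IE, -1, -2))
        m_I = m_I - np.einsum("...pq,...p->...q", gain, m_E)
        cov_I = cov_I - cov_IE @ gain
    return m_I[0], cov_I[0]


def _fc_value_batch(h: Hypothesis, mean, variances) -> np.ndarray:
    dens, prob = fit_complexity_batch(h, mean, variances)
    return dens * prob


def bf_batch(
    pair: ComparisonPair,
    centers: np.ndarray,
    obs_variances: np.ndarray,
    N: int,
    b: float,
) -> np.ndarray:
    """BF_12 for a (T, K) stack of group summaries; +inf/0 where regions vanish."""
    post_var = obs_variances / N
    prior_var = obs_variances / (b * N)
    zeros = np.zeros_like(centers)

    def bf_vs_ha(h: Hypothesis) -> np.ndarray:
        f = _fc_value_batch(h, centers, post_var)
        c = _fc_value_batch(h, zeros, prior_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            return f / c

    h1, h2 = pair.hyp1, pair.hyp2
    if h2.kind == "complement_Hc" or h1.kind == "complement_Hc":
        hyp = h1 if h2.kind == "complement_Hc" else h2
        f = _fc_value_batch(hyp, centers, post_var)
        c = _fc_value_batch(hyp, zeros, prior_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            bf_i_c = (f / c) / ((1.0 - f) / (1.0 - c))
        return bf_i_c if h2.kind == "complement_Hc" else 1.0 / bf_i_c
    bf1 = np.ones(centers.shape[0]) if not h1.is_constrained else bf_vs_ha(h1)
    bf2 = np.ones(centers.shape[0]) if not h2.is_constrained else bf_vs_ha(h2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return bf1 / bf2


def bayes_factor(
    pair: ComparisonPair,
    summaries: GroupSummaries,
    b: float,
    mc_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> BayesFactorResult:
    """AAFBF of pair.hyp1 against pair.hyp2 given group summaries.

    Against Ha the BF is fit/complexity of the constrained hypothesis;
    against the complement Hc it is (f/c) / ((1-f)/(1-c)); two constrained
    hypotheses are compared through their ratio of BFs against Ha.  A
    vanishing denominator yields a flagged +inf, never an exception.
    """
    if summaries.K != pair.K:
        raise ValueError("summaries and pair disagree on the number of groups")
    posterior, prior = approximate_distributions(summaries, b)
    one = FitComplexity(1.0, 1.0)
    h1, h2 = pair.hyp1, pair.hyp2

    if pair.situation == 3:
        hyp = h1 if h2.kind == "complement_Hc" else h2
        fit = fit_or_complexity(hyp, posterior, mc_draws, rng)
        comp = fit_or_complexity(hyp, prior, mc_draws, rng)
        f, c = fit.value, comp.value
        fit_c = FitComplexity(1.0, 1.0 - f)
        comp_c = FitComplexity(1.0, 1.0 - c)
        with np.errstate(divide="ignore", invalid="ignore"):
            bf = float(np.divide(f / c, (1.0 - f) / (1.0 - c)))
        if h2.kind != "complement_Hc":
            fit, fit_c = fit_c, fit
            comp, comp_c = comp_c, comp
            bf = 1.0 / bf if bf != 0 else math.inf
        return BayesFactorResult(
            bf_12=bf,
            bf_21=(1.0 / bf if bf != 0 else math.inf),
            fit1=fit,
            comp1=comp,
            fit2=fit_c,
            comp2=comp_c,
            b_used=b,
            infinite=not math.isfinite(bf),
        )

    fit1 = fit_or_complexity(h1, posterior, mc_draws, rng) if h1.is_constrained else one
    comp1 = fit_or_complexity(h1, prior, mc_draws, rng) if h1.is_constrained else one
    fit2 = fit_or_complexity(h2, posterior, mc_draws, rng) if h2.is_constrained else one
    comp2 = fit_or_complexity(h2, prior, mc_draws, rng) if h2.is_constrained else one
    with np.errstate(divide="ignore", invalid="ignore"):
        bf1 = fit1.value / comp1.value
        bf2 = fit2.value / comp2.value
        bf12 = float(np.divide(bf1, bf2))
    bf21 = 1.0 / bf12 if bf12 != 0 else math.inf
    return BayesFactorResult(
        bf_12=bf12,
        bf_21=bf21,
        fit1=fit1,
        comp1=comp1,
        fit2=fit2,
        comp2=comp2,
        b_used=b,
        infinite=not math.isfinite(bf12),
    )
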