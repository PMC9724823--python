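"""Simulation populations from effect sizes or explicit means.

Populations are what the sample-size search simulates from: one per
hypothesis, each giving per-group true means, variances, and optionally
skewness and excess kurtosis (for the robust, non-normal mode).  Effects may
be stated either as explicit mean vectors or as Cohen's f = sigma_m / sigma,
the standard deviation of the K group means over the (root-mean) within-group
standard deviation.  When only f is given, means are laid out equally spaced
in the order the hypothesis asserts, centred at zero, and scaled to hit f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hypotheses import Hypothesis

__all__ = [
    "PopulationSpec",
    "cohens_f",
    "means_from_f",
    "complement_population",
    "classical_sample_size",
    "resolve_populations",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Per-group true mean, variance and shape defining a simulation population."""

    means: tuple[float, ...]
    variances: tuple[float, ...]
    skewness: tuple[float, ...] = ()
    excess_kurtosis: tuple[float, ...] = ()

    def __post_init__(self):
        K = len(self.means)
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        object.__setattr__(self, "variances", tuple(float(v) for v in self.variances))
        if len(self.variances) != K:
            raise ValueError("means and variances must have equal length")
        if any(v <= 0 for v in self.variances):
            raise ValueError("variances must all be positive")
        skew = self.skewness or (0.0,) * K
        kurt = self.excess_kurtosis or (0.0,) * K
        if len(skew) != K or len(kurt) != K:
            raise ValueError("skewness/kurtosis must match the number of groups")
        for k, (s, e) in enumerate(zip(skew, kurt)):
            if e < s * s - 2:
                raise ValueError(
                    f"group {k + 1}: excess kurtosis {e} violates kurtosis >= skewness^2 - 2"
                )
        object.__setattr__(self, "skewness", tuple(float(s) for s in skew))
        object.__setattr__(self, "excess_kurtosis", tuple(float(e) for e in kurt))

    @property
    def K(self) -> int:
        return len(self.means)

    @property
    def is_normal(self) -> bool:
        return all(s == 0 for s in self.skewness) and all(e == 0 for e in self.excess_kurtosis)


def cohens_f(means, variances) -> float:
    """Cohen's f = sigma_m / sigma.

    sigma_m is the population standard deviation of the K means (divisor K);
    sigma is the square root of the arithmetic mean of the group variances,
    which reduces to the common within-group SD under homogeneity.
    """
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if m.shape != v.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("means and variances must be equal-length vectors (K >= 2)")
    if np.any(v <= 0):
        raise ValueError("variances must all be positive")
    sigma_m = np.sqrt(np.mean((m - m.mean()) ** 2))
    sigma = np.sqrt(v.mean())
    return float(sigma_m / sigma)


def _level_pattern(levels: tuple[tuple[int, ...], ...], K: int) -> np.ndarray:
    """Equally spaced level scores, largest level first, centred per group."""
    L = len(levels)
    scores = np.arange(L - 1, -1, -1, dtype=float)  # L-1 .. 0, descending
    pattern = np.empty(K)
    for score, groups in zip(scores, levels):
        for g in groups:
            pattern[g] = score
    return pattern - pattern.mean()


def means_from_f(f: float, variances, ordering) -> np.ndarray:
    """Mean vector with Cohen's f equal to ``f`` honouring an ordering.

    ``ordering`` may be ``"null"`` (zero vector, for an all-equal hypothesis),
    ``"unconstrained"``/``"ascending"`` (ascending equally spaced means, used
    for the unconstrained alternative where only the spread matters), a
    sequence of group numbers from largest to smallest mean (1-based, e.g.
    ``(2, 3, 1)`` for mu2 > mu3 > mu1), or a parsed :class:`Hypothesis` whose
    chain supplies the order.
    """
    if f < 0:
        raise ValueError("Cohen's f must be nonnegative")
    v = np.asarray(variances, dtype=float)
    K = v.size
    if np.any(v <= 0):
        raise ValueError("variances must all be positive")
    if isinstance(ordering, str) and ordering == "null":
        return np.zeros(K)

    if isinstance(ordering, Hypothesis):
        if ordering.levels is None:
            raise ValueError("hypothesis has no chain ordering to place means on")
        levels = ordering.levels
    elif isinstance(ordering, str) and ordering in ("unconstrained", "ascending"):
        levels = tuple((g,) for g in range(K - 1, -1, -1))
    else:
        perm = tuple(int(g) - 1 for g in ordering)
        if sorted(perm) != list(range(K)):
            raise ValueError(f"ordering is not a permutation of 1..{K}: {ordering}")
        levels = tuple((g,) for g in perm)

    pattern = _level_pattern(levels, K)
    spread = np.sqrt(np.mean(pattern**2))
    if spread == 0:
        if f > 0:
            raise ValueError("cannot reach f > 0 with an all-equal ordering")
        return np.zeros(K)
    sigma = np.sqrt(v.mean())
    return pattern * (f * sigma / spread)


def complement_population(means_under_hi, hi: Hypothesis) -> np.ndarray:
    """Default population for the complement Hc: the means rotated one place right.

    The rotation keeps the same spread (hence the same Cohen's f) while
    breaking the asserted order; the result is checked to actually violate
    the source hypothesis, and users can always override with explicit means.
    """
    m = np.asarray(means_under_hi, dtype=float)
    if not hi.satisfied_by(m):
        raise ValueError("means_under_hi does not satisfy the hypothesis it is meant to")
    rotated = np.roll(m, 1)
    if hi.satisfied_by(rotated):
        raise ValueError(
            "rotated means still satisfy the hypothesis (degenerate ties); "
            "specify the complement population's means explicitly"
        )
    return rotated


def resolve_populations(
    hyp1: Hypothesis,
    hyp2: Hypothesis,
    f1,
    f2,
    variances=None,
    skews=None,
    kurts=None,
) -> tuple[PopulationSpec, PopulationSpec]:
    """Populations for both hypotheses from Cohen's f values or explicit means.

    ``f1``/``f2`` are each either a scalar Cohen's f or a length-K vector of
    explicit means.  ``variances=None`` means unit variances.  A scalar f is
    laid out on the hypothesis' own ordering: zeros for an all-equal
    hypothesis, equally spaced ascending for the unconstrained alternative,
    equally spaced along the chain for an ordering; the complement Hc
    defaults to the other population's means rotated one place right.
    """
    K = hyp1.K
    v = np.ones(K) if variances is None else np.asarray(variances, dtype=float)
    if v.size != K:
        raise ValueError(f"variances must have length K={K}")
    skews = np.zeros(K) if skews is None else np.asarray(skews, dtype=float)
    kurts = np.zeros(K) if kurts is None else np.asarray(kurts, dtype=float)

    def one(hyp: Hypothesis, f, other_means):
        arr = np.atleast_1d(np.asarray(f, dtype=float))
        if arr.size == K and K > 1:
            return arr
        if arr.size != 1:
            raise ValueError(
                f"effect must be given as a scalar f or {K} means, got {arr.size} values"
            )
        fval = float(arr[0])
        if hyp.kind == "complement_Hc":
            if other_means is None:
                raise ValueError("resolve the constrained hypothesis before its complement")
            return complement_population(other_means, hyp_other)
        if hyp.kind == "unconstrained_Ha":
            return means_from_f(fval, v, "unconstrained")
        if hyp.has_inequalities:
            return means_from_f(fval, v, hyp)
        return means_from_f(fval, v, "null")

    if hyp1.kind == "complement_Hc":
        hyp_other = hyp2
        m2 = one(hyp2, f2, None)
        m1 = one(hyp1, f1, m2)
    else:
        hyp_other = hyp1
        m1 = one(hyp1, f1, None)
        m2 = one(hyp2, f2, m1)
    mk = lambda m: PopulationSpec(tuple(m), tuple(v), tuple(skews), tuple(kurts))
    return mk(m1), mk(m2)


def classical_sample_size(
    f: float, K: int, alpha: float, power: float, method: str = "ncf"
) -> int:
    """Smallest per-group n giving the one-way fixed-effects F test the target power.

    The test has df1 = K-1, df2 = K(n-1) and noncentrality lambda = f^2 K n.
    ``method="ncf"`` evaluates the exact noncentral F power; ``method="chi2"``
    uses the known-variance limit (noncentral chi-square with the central
    chi-square critical value), which is how the widely cited classical
    tables were effectively computed and can differ from the exact answer by
    one subject per group.
    """
    if not (f > 0 and K >= 2 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("require f > 0, K >= 2, alpha and power in (0, 1)")
    df1 = K - 1

    def attained(n: int) -> float:
        lam = f * f * K * n
        if method == "chi2":
            crit = stats.chi2.ppf(1 - alpha, df1)
            return float(1 - stats.ncx2.cdf(crit, df1, lam))
        df2 = K * (n - 1)
        crit = stats.f.ppf(1 - alpha, df1, df2)
        return float(1 - stats.ncf.cdf(crit, df1, df2, lam))

    # bracket by doubling, then bisect on the monotone power curve
    lo, hi = 2, 4
    while attained(hi) < power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise RuntimeError("no attainable sample size below 1e7")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if attained(mid) >= power:
            hi = mid
        else:
            lo = mid
    return hi if attained(lo) < power else lo
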