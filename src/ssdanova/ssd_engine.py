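"""Monte-Carlo sample-size search for Bayes-factor design criteria.

Given two hypotheses with their populations, the engine estimates the
exceedance probabilities

    eta1 = P(BF_12 > BF_thresh | population of H1)
    eta2 = P(BF_21 > BF_thresh | population of H2)

by simulating T datasets per population at a candidate per-group size N, and
searches for the smallest N at which both reach the requested eta.  The
search brackets by doubling N and then bisects on the conjunction of the two
criteria.  Dataset i always draws from its own deterministic substream of
the master seed, and a dataset at a smaller N is a prefix of the same
dataset at a larger N (common random numbers), which makes the conjunction
empirically monotone in N and the bisection well defined and reproducible.

When the comparison involves equality constraints, the prior fraction
b = J/(K N) is swept over the multipliers {1, 2, 3} (the 2J and 3J
sensitivity variants); Bayes factors of purely inequality-constrained
comparisons are invariant to b, so a single run is done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import datagen
from .aafbf import bf_batch, fraction_b
from .estimators import DegenerateDataError, batch_summaries
from .hypotheses import ComparisonPair
from .populations import PopulationSpec

__all__ = ["SSDConfig", "MultiplierResult", "SSDResult", "estimate_eta", "find_sample_size"]


@dataclass(frozen=True)
class SSDConfig:
    """Settings of the sample-size search.

    ``bf_thresh`` is the Bayes-factor size counted as sufficient evidence
    (>= 1); ``eta`` the required exceedance probability; ``T`` the number of
    Monte-Carlo datasets per population and candidate N; ``anova_type`` one
    of ``"equal"``, ``"unequal"``, ``"robust"``.
    """

    bf_thresh: float = 3.0
    eta: float = 0.80
    T: int = 10_000
    seed: int = 10
    anova_type: str = "equal"
    trim: float = 0.20
    mc_draws: int = 100_000
    N_min: int = 10
    N_max: int = 20_000
    multipliers: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        if self.bf_thresh < 1:
            raise ValueError("bf_thresh must be at least 1")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.T < 1 or self.N_min < 2 or self.N_max < self.N_min:
            raise ValueError("invalid T or N bounds")
        if self.anova_type not in ("equal", "unequal", "robust"):
            raise ValueError(f"unknown anova_type {self.anova_type!r}")


@dataclass(frozen=True)
class MultiplierResult:
    multiplier: int
    b: float
    N_required: int
    eta1: float
    eta2: float
    se1: float
    se2: float


@dataclass(frozen=True)
class SSDResult:
    pair: ComparisonPair
    config: SSDConfig
    per_multiplier: tuple[MultiplierResult, ...]


class NoSolutionError(RuntimeError):
    """The criteria were not met within the N cap."""

    def __init__(self, msg, eta1=None, eta2=None):
        super().__init__(msg)
        self.eta1 = eta1
        self.eta2 = eta2


class _SummaryCache:
    """Simulated summaries per (population index, N), common across multipliers.

    Dataset i of population p uses the generator seeded by SeedSequence
    (seed, spawn_key=(p, i)); standard-normal draws of shape (N, K) fill
    row-major, so the first N' rows at size N equal the whole draw at size
    N' — the common-random-numbers property the bisection relies on.
    """

    def __init__(self, populations, config: SSDConfig):
        self.populations = populations
        self.config = config
        self._store: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._gh_params = [
            None if pop.is_normal else datagen.population_params(pop) for pop in populations
        ]

    def summaries(self, pop_idx: int, N: int) -> tuple[np.ndarray, np.ndarray]:
        key = (pop_idx, N)
        if key not in self._store:
            self._store[key] = self._simulate(pop_idx, N)
        return self._store[key]

    def _simulate(self, pop_idx: int, N: int):
        cfg = self.config
        pop = self.populations[pop_idx]
        K = pop.K
        x = np.empty((cfg.T, N, K))
        for i in range(cfg.T):
            ss = np.random.SeedSequence(cfg.seed, spawn_key=(pop_idx, i))
            x[i] = np.random.Generator(np.random.PCG64(ss)).standard_normal((N, K))
        params = self._gh_params[pop_idx]
        if params is None:
            y = np.asarray(pop.means) + np.sqrt(np.asarray(pop.variances)) * x
        else:
            y = np.empty_like(x)
            for k, p in enumerate(params):
                y[:, :, k] = datagen.gh_transform(x[:, :, k], p)
        centers, obsvar = batch_summaries(y, cfg.anova_type, cfg.trim)
        bad = np.any(obsvar <= 0, axis=1)
        if bad.mean() > 0.01:
            raise DegenerateDataError(
                f"{bad.sum()} of {cfg.T} simulated datasets have a degenerate "
                "dispersion estimate; the population or N is too extreme"
            )
        return centers, obsvar


def _etas_at(pair, cache: _SummaryCache, N: int, b: float, config: SSDConfig):
    exceed = []
    for pop_idx in (0, 1):
        centers, obsvar = cache.summaries(pop_idx, N)
        bf12 = bf_batch(pair, centers, obsvar, N, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            bf = bf12 if pop_idx == 0 else 1.0 / bf12
        exceed.append(float(np.mean(bf > config.bf_thresh)))
    return exceed[0], exceed[1]


def estimate_eta(
    pair: ComparisonPair,
    pop1: PopulationSpec,
    pop2: PopulationSpec,
    N: int,
    config: SSDConfig,
    multiplier: int = 1,
) -> tuple[float, float]:
    """(eta1, eta2) at per-group size N: exceedance proportions over T datasets."""
    if N < config.N_min:
        raise ValueError(f"N={N} below configured minimum {config.N_min}")
    cache = _SummaryCache((pop1, pop2), config)
    b = fraction_b(pair.J, pair.K, N, multiplier)
    return _etas_at(pair, cache, N, b, config)


def find_sample_size(
    pair: ComparisonPair,
    pop1: PopulationSpec,
    pop2: PopulationSpec,
    config: SSDConfig | None = None,
) -> SSDResult:
    """Smallest per-group N with eta1 >= eta and eta2 >= eta, per prior multiplier.

    Brackets by doubling N from N_min until both criteria hold, then bisects
    on the conjunction using identical random substreams at every candidate
    N.  Raises :class:`NoSolutionError` (reporting the achieved etas) if the
    cap N_max is exceeded — e.g. when the two populations are too alike for
    the requested eta.
    """
    config = config or SSDConfig()
    if pop1.K != pair.K or pop2.K != pair.K:
        raise ValueError("populations and pair disagree on the number of groups")
    cache = _SummaryCache((pop1, pop2), config)
    multipliers = config.multipliers if pair.has_equalities else (1,)

    results = []
    for m in multipliers:
        def ok(N: int) -> tuple[bool, tuple[float, float]]:
            b = fraction_b(pair.J, pair.K, N, m)
            e1, e2 = _etas_at(pair, cache, N, b, config)
            return (e1 >= config.eta and e2 >= config.eta), (e1, e2)

        lo, hi = None, config.N_min
        good, etas = ok(hi)
        while not good:
            lo = hi
            hi = min(2 * hi, config.N_max)
            if lo >= config.N_max:
                raise NoSolutionError(
                    f"criteria unmet at N_max={config.N_max} "
                    f"(multiplier {m}; achieved eta1={etas[0]:.3f}, eta2={etas[1]:.3f})",
                    eta1=etas[0],
                    eta2=etas[1],
                )
            good, etas = ok(hi)
        best_N, best_etas = hi, etas
        if lo is not None:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                good, mid_etas = ok(mid)
                if good:
                    hi, best_etas = mid, mid_etas
                else:
                    lo = mid
            best_N = hi
        b = fraction_b(pair.J, pair.K, best_N, m)
        se = tuple(float(np.sqrt(e * (1 - e) / config.T)) for e in best_etas)
        results.append(
            MultiplierResult(
                multiplier=m,
                b=b,
                N_required=best_N,
                eta1=best_etas[0],
                eta2=best_etas[1],
                se1=se[0],
                se2=se[1],
            )
        )
    return SSDResult(pair=pair, config=config, per_multiplier=tuple(results))
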