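# Methods

## Model and Bayes factor

Three one-way models over K independent groups with N observations each are
supported, differing only in the summary statistics they feed forward:

* regular ANOVA — group sample means μ̂_k with one pooled unbiased residual
  variance ŝ² = Σ_k Σ_t (y_tk − μ̂_k)² / (K·N − K);
* Welch's ANOVA — group means with per-group unbiased variances ŝ²_k;
* robust ANOVA — 20% trimmed means with dispersions built from the
  Winsorized variance (below).

The posterior of μ is approximated by N(μ̂, diag(ŝ²_k/N)) (large-sample
normality), and the prior is the adjusted fractional prior
N(0, diag(ŝ²_k/(b·N))) with b = m·J/(K·N): the prior spends the information
of m·J/K observations per group, J being the rank of the union of both
hypotheses' constraint rows — the number of independent pairwise contrasts
the comparison involves — and m ∈ {1, 2, 3} the sensitivity multiplier.  The
centring at the origin of the contrast space makes the complexity an
Occam-razor measure and the Bayes factor consistent.  Reported values of b
are truncated (not rounded) to three decimals, matching the convention of
the reference outputs (e.g. 2/114 = 0.01754 reported as 0.017).

For a constrained hypothesis H_z with equality rows R_E and inequality rows
R_I, fit (under the posterior) and complexity (under the prior) are

    value = pdf_{R_E μ}(0) × P(R_I μ > 0 | R_E μ = 0),

i.e. the multivariate normal density of the equality contrasts at zero
times the conditional probability of the inequality region — the proper
limit of "proportion in agreement", which degenerates for exact equalities.
Either factor is 1 when the corresponding row set is empty.  BF_za = f_z/c_z
against the unconstrained alternative; BF_ij = (f_i/c_i)/(f_j/c_j) for two
constrained hypotheses; BF_ic = (f_i/c_i)/((1−f_i)/(1−c_i)) against the
complement.  The complement is only defined for inequality-only hypotheses
(1−f is not meaningful when f carries a density factor); pairing Hc with an
equality-carrying hypothesis is rejected.

Numerics: one inequality row uses the univariate normal CDF; two rows use
the exact bivariate normal CDF via Owen's T function (with explicit
handling of zero arguments — the generic case for zero-centred priors — and
of the both-zero corner, Φ₂(0,0,ρ) = 1/4 + arcsin ρ / 2π); three or more
rows fall back to scrambled-Sobol quasi-Monte Carlo (default 10⁵ draws)
with a binomial-style standard error attached.  K = 3 designs are therefore
fully deterministic given the simulated data.  Vanishing fits or
complexities yield flagged ±inf/0 Bayes factors, never exceptions, so they
count correctly in exceedance proportions.

Because zero-centred normal orthant probabilities are scale-invariant,
Bayes factors of comparisons without equality constraints are exactly
invariant to b; the sensitivity sweep over m is accordingly run only when
the pair carries at least one equality row.

## Robust summaries

With g = floor(0.2·N) (Wilcox's convention), the trimmed mean averages the
N − 2g central order statistics; the Winsorized variance s²_w is the
unbiased variance of the sample with its g smallest values replaced by the
(g+1)-th and its g largest by the (N−g)-th order statistic.  The estimated
variance of the trimmed mean is s²_w/((1 − 2·0.2)²·N), so the
per-observation dispersion fed to the posterior is s²_w/0.36.  For standard
normal data s²_w converges to 0.6 − 2cφ(c) + 0.4c² ≈ 0.41209 with
c = Φ⁻¹(0.8), giving a per-observation dispersion of ≈ 1.1447; the test
suite checks this limit by simulation.  The trim fraction is configurable;
0.2 is the default throughout.

## Populations and effect sizes

Cohen's f = σ_m/σ, with σ_m the population SD (divisor K) of the K means
and σ = sqrt(mean of the group variances), which reduces to the common
within-group SD under homogeneity and reproduces the reference effect sizes
exactly under heteroscedasticity.  When a population is specified only by
f, means are equally spaced on the hypothesis's chain (tied groups share a
level), centred at zero and scaled to hit f; for the unconstrained
alternative the ascending arrangement is used (only the spread matters for
equality-vs-unconstrained comparisons); for an all-equal hypothesis f must
be 0 and the means are zero.  Equal spacing is the symmetric canonical
choice; reference configurations with other spacings require explicit mean
vectors, which every entry point accepts.  The default complement
population rotates the ordered means one place to the right — preserving
spread, hence f, while breaking the order — and the rotation is verified to
violate the source hypothesis (degenerate tie cases must supply explicit
means).  For two competing orderings specified only by f, the second
hypothesis's population uses the same equally spaced values arranged per
its own chain; the cyclic-rotation pair (e.g. μ1>μ2>μ3 vs μ2>μ3>μ1) is the
configuration under which the reference sample size for
ordering-vs-ordering designs (N = 13 at f = 0.25) is reproduced.

Non-normal populations use the Tukey g-and-h transform
T(X) = A + B·e^{hX²/2}(e^{gX}−1)/g of a standard normal (the g → 0 limit
A + B·e^{hX²/2}X is taken exactly at g = 0).  Raw moments of the base
variate have a closed form valid for h < 1/n; (g, h) are solved from target
skewness and excess kurtosis by bounded least squares (|g| kept away from
the catastrophic-cancellation region near 0; the symmetric case is solved
one-dimensionally in h, where excess kurtosis is increasing on h ≥ 0 and
bounded below by ≈ −1.55 on the lighter-tailed side).  (A, B) are then
calibrated so the population mean and variance of T(X) match the requested
group mean and variance — the raw moments, not the trimmed/Winsorized ones.
This choice keeps Cohen's f interpretable exactly as specified, but note
that for skewed populations the trimmed centres the robust ANOVA compares
are shifted relative to the raw means, and shifted differently across
groups with different skewness; robust designs for skewed data are
therefore sensitive to this calibration convention, and reference robust
sample sizes built under a different (undocumented) convention can differ
substantially (the skewed-salaries worked example reproduces direction and
b arithmetic but not the reference N).  Feasibility requires
excess kurtosis ≥ skewness² − 2 and a solution with h < 1/4 (finite fourth
moment); infeasible targets raise a descriptive error.

## Sample-size search

At a candidate N, T datasets are simulated from each hypothesis's
population; dataset i of population p draws from the substream
SeedSequence(seed, spawn_key=(p, i)), and standard-normal draws of shape
(N, K) fill row-major, so the dataset at a smaller N is a prefix of the
same dataset at a larger N.  These common random numbers make the
"both criteria hold" predicate empirically monotone in N, so the search —
doubling from N_min = 10 until both exceedance proportions reach η, then
bisecting — is well defined and reproducible; by construction at least one
criterion fails at N − 1 under the same streams.  Exceedance probabilities
are plain proportions of BF > BF_thresh over the T replicates, reported
with the binomial standard error sqrt(η(1−η)/T).  Simulated summaries are
cached per (population, N) and shared across the multiplier sweep, whose
Bayes factors differ only through b.  Defaults: BF_thresh = 3, η = 0.8,
T = 10000, seed = 10, N_max = 20000 (a guard against unattainable criteria,
e.g. two identical populations with η > 0.5 both ways, which raise a
no-solution error reporting the achieved probabilities).  N_min = 10 also
guarantees ≥ 6 observations survive 20% trimming in robust mode.

At T = 10000 the returned N is stable to within about ±2 across seeds for
the designs exercised in the tests; the acceptance suite asserts ±3.

## Classical comparator

`classical_sample_size` returns the smallest per-group n for which the
one-way fixed-effects F test (df1 = K−1, df2 = K(n−1), noncentrality
λ = f²·K·n) reaches the target power.  The exact noncentral-F computation
gives 323/53/22 at f = 0.1/0.25/0.4 (K = 3, α = 0.05, power 0.8); the
widely cited classical tables print 322/52/21, which the known-variance
limit (noncentral χ² against the central χ² critical value,
`method="chi2"`) reproduces exactly.  Both are exposed; the exact
computation is the default.

## What the simulations do and do not show

The generator draws i.i.d. observations per group from exactly the families
the models assume (normal, or g-and-h with specified shape), with equal N
per group and independent groups.  Passing tests therefore establish the
correctness of the Bayes factor arithmetic and the search, and the
operating characteristics under the stated populations — not robustness to
misspecification beyond what the robust mode models (no dependence,
missingness, unequal allocation, or outlier mixtures other than what
trimming absorbs).  Anticipated means, variances and shapes are design
inputs; if they are wrong, the planned N inherits the error.

## Known limitations

* Only pairwise ±1 contrasts on group means (chains); no coefficients,
  constants, or constraints on other parameters.
* Equal per-group allocation only.
* The complement Hc requires an inequality-only partner hypothesis.
* Robust designs for skewed populations depend on the raw-moment
  calibration convention discussed above.
* Sequential updating is out of scope: a fixed-N design can be combined
  with interim Bayes-factor monitoring, but no stopping-rule operating
  characteristics are computed here.
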