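"""Robust design for skewed salary-like data: two competing orderings.

Salaries in three age bands are right-skewed (skewness 2/2.5/1.75, excess
kurtosis 6/10/6) with unequal variances, so data are simulated from
moment-matched Tukey g-and-h populations and summarised by 20% trimmed
means with Winsorized dispersions.  Two orderings compete (mu2>mu3>mu1 vs
mu3>mu2>mu1) at effect size f = 0.25; any positive Bayes factor should pick
the right one with probability 0.9 (threshold 1).
"""

from ssdanova import (
    SSDConfig,
    build_pair,
    find_sample_size,
    format_b,
    parse_hypothesis,
    resolve_populations,
)

h1 = parse_hypothesis("mu2>mu3>mu1", 3)
h2 = parse_hypothesis("mu3>mu2>mu1", 3)
pair = build_pair(h1, h2)
pop1, pop2 = resolve_populations(
    h1, h2, 0.25, 0.25, (1.5, 0.75, 0.75), skews=(2, 2.5, 1.75), kurts=(6, 10, 6)
)
print("population means under H1:", tuple(round(m, 3) for m in pop1.means))

cfg = SSDConfig(bf_thresh=1.0, eta=0.90, T=2000, seed=10, anova_type="robust")
result = find_sample_size(pair, pop1, pop2, cfg)
blk = result.per_multiplier[0]
print(f"using N = {blk.N_required} and b = {format_b(blk.b)}")
print(f"P(BF12>1|H1)={blk.eta1:.3f}")
print(f"P(BF21>1|H2)={blk.eta2:.3f}")

print(
    "\nN is the respondents per age band so that the trimmed-mean Bayes\n"
    "factor identifies the true ordering with probability 0.9, with the\n"
    "populations calibrated to the raw means/variances stated above."
)
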