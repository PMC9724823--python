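# ssdanova

Sample size determination for Bayesian one-way ANOVAs with informative
hypotheses.

Researchers comparing K group means often hold expectations sharper than
"not all means are equal": equality constraints (H0: μ1 = μ2 = μ3) or order
constraints (H1: μ3 > μ2 > μ1), possibly mixed (μ1 > μ2 = μ3).  The
approximate adjusted fractional Bayes factor (AAFBF) quantifies the evidence
between two such hypotheses as

    BF_za = f_z / c_z,

where the *fit* f_z is the share of a normal approximation to the posterior
of μ = (μ1 … μK) in agreement with H_z and the *complexity* c_z is the same
share of a fractional prior.  The posterior approximation is
N(μ̂, diag(ŝ²_k / N)); the prior is centred at the origin with variances
ŝ²_k / (b·N), where the fraction b = J/(K·N) reserves the information of
J/K observations per group, J being the number of independent constraints of
the comparison (2J and 3J variants probe prior sensitivity).  Two
constrained hypotheses are compared through BF_ij = BF_ia / BF_ja, and an
ordering against its complement by BF_ic = (f_i/c_i) / ((1−f_i)/(1−c_i)).

The design question this package answers: what is the smallest per-group N
such that

    P(BF_12 > BF_thresh | H1 true) ≥ η   and   P(BF_21 > BF_thresh | H2 true) ≥ η ?

The probabilities are estimated by simulating T datasets per candidate N
from populations matching each hypothesis (specified by Cohen's f or by
explicit means and variances), and the minimal N is found by doubling then
bisecting with common random numbers.  Three ANOVA flavours are supported:

* **equal** — homogeneous variances, pooled residual variance;
* **unequal** — Welch-type groupwise variances;
* **robust** — 20% trimmed means with Winsorized-variance dispersions, with
  data drawn from moment-matched Tukey g-and-h populations when skewness
  and excess kurtosis are specified.

## Worked example

How many students per group to compare three teaching methods with
anticipated mean math scores 550/560/580, common SD 50 (Cohen's f ≈ 0.25),
testing H0 against the ordering μ3 > μ2 > μ1 with threshold 3 and η = 0.8?

```python
from ssdanova import (SSDConfig, build_pair, find_sample_size, format_b,
                      parse_hypothesis, resolve_populations)

h0 = parse_hypothesis("mu1=mu2=mu3", 3)
h1 = parse_hypothesis("mu3>mu2>mu1", 3)
pair = build_pair(h0, h1)
pop0, pop1 = resolve_populations(h0, h1, (0, 0, 0), (550, 560, 580), (2500,) * 3)
result = find_sample_size(pair, pop0, pop1, SSDConfig(T=10_000, seed=10))
for blk in result.per_multiplier:
    print(f"using N = {blk.N_required} and b = {format_b(blk.b)}")
    print(f"P(BF01>3|H0)={blk.eta1:.3f}")
    print(f"P(BF10>3|H1)={blk.eta2:.3f}")
```

prints

```
using N = 72 and b = 0.009
P(BF01>3|H0)=0.975
P(BF10>3|H1)=0.804
using N = 61 and b = 0.021
P(BF01>3|H0)=0.943
P(BF10>3|H1)=0.800
using N = 55 and b = 0.036
P(BF01>3|H0)=0.912
P(BF10>3|H1)=0.807
```

Each block is one prior-fraction setting (b, 2b, 3b): between 55 and 72
students per group are needed, with the exact number depending on how much
information the prior borrows; the two probabilities confirm that at the
returned N the Bayes factor exceeds 3 with probability ≥ 0.8 under either
hypothesis.  Because wider priors favour the null, the required N shrinks as
the multiplier grows; order-only comparisons are invariant to b and report a
single block.

The same machinery runs from the shell:

```bash
ssd anova --hyp1 "mu1=mu2=mu3" --hyp2 "mu3>mu2>mu1" \
    --f1 0,0,0 --f2 550,560,580 --var 2500,2500,2500 --type equal
ssd anova-robust --hyp1 "mu2>mu3>mu1" --hyp2 "mu3>mu2>mu1" \
    --f1 0.25 --f2 0.25 --var 1.5,0.75,0.75 --skews 2,2.5,1.75 --kurts 6,10,6 \
    --bf-thresh 1 --eta 0.9
ssd bf data.csv --hyp1 "mu1>mu2>mu3" --hyp2 "Hc"   # BF on observed data
```

and the `examples/` directory holds one short narrative script per
capability (design for null-vs-ordering, Welch complement designs, robust
skewed designs, Bayes factors on observed data, effect-size translation and
the classical power comparator).

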