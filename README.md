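# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of one trait (the *exposure*) on
another (the *outcome*) using germline genetic variants as instrumental
variables, needing only published GWAS summary statistics from two
non-overlapping study populations. It was built around the question of
whether genetic liability to cancer causally lowers the risk of
Alzheimer's disease — an inverse association long reported in
observational cohorts but vulnerable to confounding, survival bias and
reverse causation — and works for any binary-exposure / binary-outcome
pair analysed the same way.

The intended users are genetic epidemiologists who have, per candidate
instrument SNP *j*, an exposure effect estimate and an outcome effect
estimate, and who want the full summary-data MR workflow as an
importable Python library: instrument selection, allele harmonization,
pooled causal estimation, pleiotropy diagnostics, and a Bayesian check
on whether a "significant" finding is worth believing.

## The model

Each instrument gives a Wald ratio estimate of the causal log-odds
effect θ of the exposure on the outcome:

```
θ̂_j = β̂_Yj / β̂_Xj,        var(θ̂_j) = se(β̂_Yj)² / β̂_Xj²
```

using first-order weights (the NOME approximation: exposure effects from
large discovery GWAS are treated as measured without error). The pooled
fixed-effect inverse-variance weighted (IVW) estimate is

```
θ̂_IVW = Σ_j w_j θ̂_j / Σ_j w_j ,   w_j = 1/var(θ̂_j),   se(θ̂_IVW) = (Σ_j w_j)^(-1/2)
```

which is identical to the zero-intercept weighted least-squares slope of
β̂_Y on β̂_X with weights se(β̂_Y)⁻². `exp(θ̂_IVW)` is the odds ratio for
the outcome per 1-unit increase in the log odds of the exposure.

Validity rests on the three instrumental-variable assumptions: variants
are associated with the exposure, independent of confounders, and affect
the outcome only through the exposure. The package probes the third with
MR-Egger regression (a weighted fit of β̂_Y on β̂_X *with* an intercept;
a non-zero intercept indicates directional pleiotropy), Cochran's Q for
heterogeneity of the ratios, leave-one-out re-estimation, and funnel
(effect vs. instrument strength) data. A false-positive report
probability / Bayesian false-discovery grid over priors
{50%, 10%, 1%, 0.1%} quantifies how believable each result is.

## Worked example

```python
import math
from tsmr import SyntheticScenario, harmonize, ivw_pool, simulate_two_sample, wald_ratio

scenario = SyntheticScenario(n_snps=50, theta_true=math.log(0.95), seed=20190919)
exposure, outcome = simulate_two_sample(scenario)
harmonized, dropped = harmonize(exposure, outcome)
result = ivw_pool([wald_ratio(h) for h in harmonized], group="synthetic exposure")
```

Running `python examples/01_simulate_and_estimate.py` (which is exactly
this) prints:

```
harmonized 50 instruments (22 needed an allele flip)
true OR       0.950
estimated OR  0.933 (95% CI 0.896-0.971, p = 0.000633)
heterogeneity Q = 66.24 (p = 0.051)
```

The estimated odds ratio of 0.933 recovers the simulated 0.950 within
its confidence interval — each unit of genetically predicted exposure
log-odds multiplies the outcome odds by ~0.93 — and the borderline Q
reflects ordinary sampling noise, not pleiotropy. The other examples
cover the sensitivity suite under injected directional pleiotropy
(`02`), the false-discovery grid (`03`), and the file-based pipeline at
the published analysis scale of 18–314 instruments per group (`04`),
which can also be driven from the shell:

```bash
tsmr simulate --n-snps 50 --theta-true -0.05 --out-dir data/
tsmr run-all --config analysis.yaml
```

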