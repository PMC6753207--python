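# Methods

## Statistical model

The package implements summary-data two-sample Mendelian randomization
for a binary exposure and binary outcome. For instrument *j*, let β̂_Xj
be the per-allele log-odds effect on the exposure with standard error
se(β̂_Xj), and β̂_Yj / se(β̂_Yj) the analogous outcome quantities from an
independent sample. The per-SNP causal estimate is the Wald ratio
θ̂_j = β̂_Yj / β̂_Xj with first-order variance se(β̂_Yj)²/β̂_Xj². First-
order weights embody the NOME assumption — no measurement error in the
exposure effects — which is reasonable when instruments come from very
large discovery GWAS; violating it attenuates estimates toward the null
(weak-instrument bias), which the generator can demonstrate by setting
`nome=False`.

The pooled estimate is the fixed-effect inverse-variance weighted mean
of the ratios. Writing w_j = β̂²_Xj · se(β̂_Yj)⁻², the weighted-mean form
Σw_jθ̂_j/Σw_j is algebraically the ratio of weighted cross-products
Σβ̂_Yjβ̂_Xj se(β̂_Yj)⁻² / Σβ̂²_Xj se(β̂_Yj)⁻², and equals the
zero-intercept weighted least-squares slope of β̂_Y on β̂_X with weights
se(β̂_Y)⁻². The test suite verifies all three routes agree to 1e-10 or
better. The fixed-effect model assumes one shared causal effect across
instruments; Cochran's Q flags departures from it.

### Inference conventions

- `se(θ̂_IVW) = (Σw_j)⁻¹ᐟ²`, the standard fixed-effect meta-analysis
  companion to the estimator.
- IVW p-values come from the standard normal (fixed-effect weights are
  treated as known), two-sided.
- 95% CIs exponentiate θ̂ ± 1.959964·se. The multiplier is kept at full
  precision, rather than 1.96, so CIs rounded to two decimals match
  meta-analysis tables; all rounding happens only in the reporting
  layer (`report.py`).
- MR-Egger fits β̂_Y = a + b·β̂_X by weighted least squares with weights
  se(β̂_Y)⁻², after re-orienting every instrument to β̂_X ≥ 0 (flipping
  β̂_Y in tandem) — the orientation in which the intercept estimates
  average directional pleiotropy. Standard errors use the estimated
  residual scale (weighted RSS/(J−2), i.e. multiplicative dispersion)
  and inference is Student t with J−2 degrees of freedom. With small
  instrument counts (the smallest multi-SNP group analysed has 11) the
  t reference differs materially from the normal; the t choice matches
  the weighted-`lm` convention of the standard R tooling and makes the
  intercept test exactly calibrated when outcome SEs are constant.
- Cochran's Q = Σw_j(θ̂_j − θ̂_IVW)² uses the same first-order weights
  and a χ²(J−1) reference.
- Q, leave-one-out and funnel outputs are pure functions of the
  harmonized set; reruns are byte-identical.

### Group pooling

Results are produced per cancer type and for pooled sets (smoking-
related, non-smoking-related, all). Instruments are concatenated across
the cancers in a pooled group, and an rsid instrumenting two cancers
contributes one row per cancer: the published group arithmetic
(68 + 246 = 314) implies no cross-cancer de-duplication, so that is the
default, with a `dedupe` switch for the alternative. A group needs ≥2
instruments for a pooled result (a single-instrument cancer is reported
through its Wald ratio and still joins the pooled groups) and ≥3 for
MR-Egger and leave-one-out.

## Instrument selection

Three rules, applied in order per cancer type:

1. **Significance**: keep SNPs with exposure association p strictly
   below 5×10⁻⁸ (a SNP at exactly the threshold is dropped).
2. **LD pruning** (r² < 0.2 required): greedy lead-SNP selection —
   visit SNPs in ascending p-value (ties broken lexicographically by
   rsid, for determinism), accept the best remaining SNP, discard all
   remaining SNPs with r² ≥ 0.2 against it. The retained set never
   contains a violating pair and is invariant to input row order.
   Pruning is within one cancer type only.
3. **Proxy substitution**: an instrument absent from the outcome data
   is replaced by its highest-r² proxy with r² strictly > 0.9 that is
   present in the outcome data; exposure beta/se/p are inherited from
   the target (only alleles are reassigned, through the supplied
   target→proxy allele bijection). Absent instruments with no
   qualifying proxy are dropped and reported. No transitive
   proxy-of-proxy search.

Every input rsid lands in exactly one bin of the selection report
(kept / failed significance / pruned-for-LD / proxied / no proxy),
which serializes to JSON.

## Harmonization

Exposure and outcome records are joined on SNP id (an opaque key: rsID
or chromosome:position both work) and aligned to the exposure's effect
allele, case-insensitively. A swapped outcome allele pair negates the
outcome beta (never its magnitude or SE); an irreconcilable pair drops
the SNP with reason "incompatible". Palindromic (A/T, C/G) variants are
retained with a flag by default — no strand inference from allele
frequency is attempted, since frequencies are often absent from
instrument tables — with a `drop_palindromic` switch as the
conservative alternative. Harmonization is idempotent, and the Wald
ratio is invariant to which allele is labelled "effect" (double sign
flip cancels).

## False-discovery assessment

Each group result gets a posterior false-discovery probability at
priors π₁ ∈ {0.5, 0.1, 0.01, 0.001} that the null is false, computed
irrespective of significance. The default construction is the FPRP,

    FPRP = α·π₀ / (α·π₀ + power·π₁),  π₀ = 1 − π₁,

with α set to the observed p-value (each result gets its own level) and
power the probability of attaining p ≤ α when the true effect equals
the observed estimate, from two-sided normal tails. The FPRP was chosen
as the default because it is the construction that combines exactly a
p-value and study power with the prior. A Bayes-factor alternative
(BFDP) with a normal prior of variance W on the effect under the
alternative is provided alongside; its default W places 95% of prior
mass on odds ratios between 1/1.5 and 1.5. The two constructions answer
slightly different questions and their numbers differ — sometimes
several-fold — but both are monotone in the evidence and in the prior,
which the tests verify. Published per-result BFDR figures in this
design space depend on an unstated power convention (the alternative
effect size and sidedness), so no attempt is made to match any
particular printed grid; percentages are a reporting-layer format.

## Synthetic data generator

`simulate_two_sample` emulates the inputs of a real analysis: J
instruments with true exposure effects drawn from N(0, beta_x_scale²)
and magnitude-floored at 0.01 (ratios must not degenerate), outcome
effects θ_true·β_Xj + α_j + ε_j with ε_j ~ N(0, se_y²), alleles as
random A/C/G/T pairs with ~half the outcome rows reported in the
swapped orientation (so harmonization is actually exercised), and
p-values from normal tails. Pleiotropic intercepts α_j are zero
(`none`), N(0, sd) (`balanced`) or N(mean, sd) (`directional`), acting
in the exposure-raising allele orientation — the orientation in which
the Egger intercept is defined — so that allele recoding flips β_X, β_Y
and α coherently. NOME is the default, consistent with first-order
weights.

Default scales: `beta_x_scale = 0.1` (cancer susceptibility loci
typically carry per-allele log-odds effects of 0.05–0.3), `se_x = 0.01`
(discovery GWAS of 10⁵-scale samples), `se_y = 0.015` (a case-control
outcome meta-analysis of ~50k samples). With these defaults a 314-
instrument pooled analysis has se(θ̂_IVW) ≈ 0.009, matching the CI
widths of published analyses at that scale. The documentation seed
20190919 is fixed once.

`simulate_ld_fixture` produces block-diagonal LD (constant r² within a
locus, zero across) with one designated "missing" SNP per locus mapped
to an in-block proxy. `paper_scale_scenario` returns six presets sized
like the published analysis groups (J = 18, 38, 109, 68, 246, 314) with
true effects ln(0.91), ln(0.98), ln(0.94), ln(0.95), ln(0.98), ln(0.98),
with disjoint rsid ranges so the six exposure tables share one outcome
table.

**What the generator does not emulate** — and therefore what passing
tests cannot certify about real data: realistic LD from population
haplotypes (blocks are idealized), allele-frequency-dependent standard
errors, winner's-curse inflation of discovery betas, sample overlap
between the two studies, population stratification, and misclassified
or heterogeneous outcome phenotypes. Calibration results here validate
the estimators under their own assumptions, not the robustness of any
substantive finding.

## Calibration studies

`tsmr.calibration` runs the Monte-Carlo studies the acceptance checks
use, on raw effect arrays for speed. Replicate counts — 200 instrument
sets for the WLS-oracle comparison, 1,000 replicates for bias/coverage,
5,000 for the Egger type-I error and Q rejection rate, 2,000 for
directional-intercept recovery — were sized so Monte-Carlo standard
errors are a few parts in a thousand and each study completes in
seconds. Under the balanced-pleiotropy scenario with constant outcome
SEs the Egger residuals are exactly i.i.d. normal, so the t-based
intercept test is exactly calibrated and the observed type-I error
should sit within simulation error of 0.05; the same argument makes Q
exactly χ²(J−1) in the homogeneous NOME scenario.

## Degenerate inputs and edge policies

- β̂_X = 0 → undefined Wald ratio, raised as an error per SNP and
  excluded upstream of Egger.
- One instrument → no pooled result (the Wald ratio itself is the
  estimate); two → IVW but no Egger/leave-one-out.
- Empty outcome overlap → empty results with an explicit diagnostic,
  not an exception.
- p-value ties in pruning and r² ties in proxy choice break
  lexicographically by rsid.
- Exact thresholds: significance and proxy rules are strict
  inequalities; the pruning rule discards at r² ≥ threshold.
- File round trips use 17-significant-digit floats (lossless for
  float64).

## Known limitations

Only SNP instruments (single-character alleles); no multi-allelic or
indel support, no genome-build liftover, no strand inference for
palindromic variants, no r² computation from genotype panels, no
random-effects IVW, weighted-median/mode estimators, or multivariable
MR. Binary exposures dichotomize a latent liability, so the numeric
effect size has the usual interpretation caveats even when the causal
null-hypothesis test is valid.
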