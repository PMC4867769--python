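# Methods

## The design and its statistics

All inference is within-pair. For a discordant MZ pair *i* at probe *j* the
unit of analysis is d_ij = β_affected,ij − β_unaffected,ij; everything
pair-constant (genotype, age, sex, shared environment, chip — pairs are
assumed co-processed) cancels in d. The scan tests H0: E[d_j] = 0 with the
one-sample ("paired") t statistic t_j = mean(d_j)/(sd(d_j)/√n), df = n − 1,
two-sided. No genome-wide multiplicity correction is applied at discovery;
two threshold views are reported (primary P < 5×10⁻⁵, extended P < 10⁻³),
ranked by P with ties broken by |Δβ| descending, then probe id. Both signs
of Δβ are meaningful, hence two-sided tests throughout.

**Empirical P.** The only exchangeability a discordant design grants is
within-pair label exchange, so the permutation null flips the sign of each
d_ij independently (equivalently: re-assigns affected/unaffected within each
pair). Two counting rules are computed per probe over n_perm = 10,000
permutations: the primary rule counts permutations whose paired-test P falls
below the fixed significance threshold 5×10⁻⁵ ("at least as significant as
the true result" with the published fixed-event reading); the secondary rule
counts P_perm ≤ P_observed (the conventional definition). Both are reported;
neither adds the identity permutation to the numerator, so the resolution is
1/n_perm. When 2^n_pairs ≤ n_perm the flips are enumerated exhaustively and
the empirical P is exact. Because the sign flip leaves Σd² unchanged, the
permutation t reduces to a function of the permuted mean only, which keeps
the 10,000 × probes computation a single matrix product.

**Inflation diagnostic.** λ = median(χ²₁-quantile of P)/0.45494, with a Q-Q
table (expected vs observed −log₁₀P) emitted for plotting. λ ≈ 1 on null
data; the test suite checks this on uniform P draws (tolerance 0.03).

**Covariate adjustment** regresses raw β on the covariates (OLS with
intercept, per probe, across all samples) and carries residual + grand mean
forward, so the paired test runs unchanged on adjusted values. Whether the
original analyses residualized raw β or within-pair differences is not
documented anywhere we could rely on; raw-β residualization was chosen
because it also adjusts the group means that the discovery table reports.
Collinear covariates are dropped with a warning.

**Specificity.** For concordant unaffected pairs "affected minus
unaffected" is undefined, so each of 1,000 permutations assigns random
Twin1/Twin2 labels and the signed within-pair Δβ = β₁ − β₂ is averaged per
pair across permutations. The signed average converges to 0 by symmetry —
informative as a sanity check, degenerate as a comparison group — so the
default comparison uses the orientation-free absolute value (whose
permutation average equals the pair's |β₁ − β₂| exactly). The test is a
Welch two-sample t between the discordant pairs' per-pair values (n = 24)
and the concordant pairs' per-pair averages (n = 20): per-pair units in both
groups, avoiding pseudo-replication across permutations; group variances
differ by construction, hence Welch rather than pooled. Both variants are
emitted.

**Longitudinal contrast.** Per individual, longitudinal Δβ = β_age10 −
β_age5 (individuals matched by sample id across waves); per pair, D_i =
Δβ_affected,i − Δβ_unaffected,i; the one-sample t on D is algebraically the
paired test and is implemented by the same routine (the suite asserts exact
equality). Only probes passing QC in both waves and pairs complete in both
waves contribute.

**Enrichment.** Gene universe = genes with ≥ 1 retained probe; a gene is
"DE" when annotated to ≥ 1 probe passing the extended threshold (a probe
annotated to several genes counts for each). The probability weighting
function is an isotonic (pool-adjacent-violators) regression of the DE
indicator on per-gene probe count, clipped to [1/(2N), 1 − 1/(2N)] —
parameter-free and monotone by construction, a deliberate variant of the
monotone-spline fit used by the GOseq family. Category P values use the
Wallenius noncentral hypergeometric upper tail with odds
(w̄_in/(1 − w̄_in))/(w̄_out/(1 − w̄_out)); with constant weights this is
exactly the one-sided Fisher test, and the suite cross-checks the biased
case against a weighted-resampling (Efraimidis–Spirakis) oracle. One-sided
over-representation only; Bonferroni across tested terms.

**Replication meta-analysis.** Per cohort, MD = mean_case − mean_control
(β is already a common scale — no standardization) and SE =
√(sd²_case/n_case + sd²_control/n_control). Fixed-effects pooling with
w_k = 1/SE_k², pooled SE = 1/√Σw, normal-approximation z inference (the
standard choice for summary-level pooling), Q = Σw_k(MD_k − pooled)² on
k − 1 df, I² = max(0, (Q − df)/Q)·100. Candidate-set Bonferroni adjustment
uses the number of candidates carried into replication by default; the
denominator is configurable because published Bonferroni ratios in this
literature often imply candidate counts that are never printed.

## QC and normalization

A probe-call fails for a sample when detection P ≥ 0.05 or bead count < 3;
a sample is removed when > 5% of its calls fail, together with its co-twin
(an unpaired twin carries no within-pair information). The detection-P
direction follows the standard convention (high detection P = signal
indistinguishable from background = failed call); the direction is
configurable because the opposite reading circulates in print. Probe
filters: cross-reactive, chromosome X/Y, SNP control, and any probe with a
missing value in a retained sample (complete-case — paired statistics are
undefined on incomplete pairs). Filters are idempotent. The 65 genotype-like
SNP control probes are excluded from testing but retained for the
monozygosity check: a pair passes when its mean absolute within-pair
difference at those probes is ≤ 0.1 (independently drawn genotype profiles
sit near 0.3–0.5); failures are flagged, never auto-removed.

Normalization follows the dasen recipe in spirit, not byte-for-byte: per
sample and channel, type I intensities are shifted so their 5th percentile
(a background proxy) matches the type II 5th percentile, floored at zero;
then between-sample quantile normalization (rank-wise means of the sorted
columns, ties averaged — deterministic) is applied separately within each of
the four {M, U} × {type I, II} strata. β = M/(M + U + offset) with the
platform-standard offset 100.

## The synthetic-data generator

The generator produces what the analyses consume, with the statistical
structure they assume; its defaults are the study conditions (24 discordant
+ 20 concordant pairs at age 10, 18 discordant pairs at age 5, 20,000
probes, 20 spiked effects with |Δβ| ∈ [0.02, 0.09], 65 SNP controls, two
brain cohorts of 20/23 and 18/15).

*Baselines.* Per-probe means are drawn on the logit scale from a three-part
mixture — hypomethylated (weight 0.35, centre β = 0.10), hypermethylated
(0.45, centre 0.90), intermediate (0.20, centre 0.50) — giving the canonical
bimodal beta distribution.

*Variance components.* Individual values are logit(β) = μ_j + a_pj + e_ij
with a pair-shared effect a ~ N(0, σ_pair²) and individual noise
e ~ N(0, s_j²), mapped back through the logistic function (no truncation
artifacts). Noise is deliberately heterogeneous across probes: most CpGs are
tight (s_j = σ_noise = 0.12 logit units, i.e. β-scale noise ≈ 0.01–0.03
depending on the baseline slope) while a 10% hypervariable fraction carries
~9× that. This is the only noise structure consistent with the two facts
such a study exhibits at once: an across-probe co-twin profile correlation
of r ≈ 0.98 (which fixes the *total* discordance variance) and top-hit test
statistics implying per-pair Δβ SDs of only ~0.02–0.03 at individual CpGs
(which bound the *typical* probe's noise far below the average). A constant
noise scale cannot satisfy both; heterogeneous per-CpG variance is also what
real 450K data show. The hypervariable scale (9.25) was calibrated once, by
the documented `calibration_summary` helper, to hit mean within-pair
r = 0.98 over seeds 1–10 at defaults; σ_pair = 0.12 models shared
familial/technical variation and contributes to the correlation, not to
within-pair differences.

*Spiked effects.* Spiked probes are drawn from the intermediate component at
typical (non-hypervariable) CpGs — re-drawn if the baseline would saturate —
and the affected twin's logit mean is shifted so the expected β-scale Δβ
equals the drawn δ exactly (Gauss–Hermite expectation of the logistic under
the total perturbation SD, solved by Brent's method; sign randomized). The
suite verifies the empirical mean Δβ at δ = 0.05 lands within 0.005 at 500
pairs. With `persistence` > 0 an attenuated shift (re-solved for
persistence·δ) is present at age 5; at persistence = 1 the longitudinal
contrast is null at spiked probes, which the suite checks.

*Artifacts.* Detection P values are ~U(0, 0.01) with 0.5% sporadic failures
and bead counts 3 + Poisson(11) with 0.2% low-bead events (per-sample
failure fractions ~0.7%, below the 5% removal rule); `inject_qc_failures`
pushes chosen samples to an 8% failing fraction to trip the filter. SNP
control probes take genotype-like values near {0.05, 0.5, 0.95}, identical
within a pair up to 0.01 measurement noise. Intensities are reconstructed
from β (lognormal totals around 5,000 with per-sample scale factors and a
+600 type I background) so the normalization stage has real work to do;
covariates (internalizing, externalizing, depression) are generated
independent of spike status. One global seed drives named RNG streams, one
per artifact, so each artifact is reproducible independently of generation
order.

*What the generator does not emulate* — and hence what passing tests do not
establish about real data: batch/chip effects, cell-type heterogeneity,
spatial correlation between neighbouring probes, genotype-driven
(meQTL) methylation structure beyond the SNP controls, and raw two-channel
fluorescence. The generator's probes are exchangeable given their variance
tier; real arrays are not.

## Numerical and degenerate-input choices

Zero-variance deltas: t = 0, P = 1 when the mean is also zero; flagged
degenerate with P missing otherwise. Zero-variance permutations are scored
maximally extreme. Specificity tests with zero variance in both groups are
flagged, not scored. Quantile-normalization ties take the mean of the tied
ranks' reference values. β values written to text use 17 significant digits
and are parsed with round-trip float precision, so read(write(x)) is
bit-exact. Wallenius odds are guarded by the PWF clip (no gene has weight
exactly 0 or 1); terms covering the whole universe are rejected. Empirical-P
probe sets are reduced to pairs complete across the set. Bonferroni is
min(1, nP).

## Problem sizes used by the checks

The test suite exercises the full study geometry (24/20/18 pairs) with probe
counts between 300 and 20,000 chosen per check: generator calibration runs
ten seeds at the full 20,000 probes; null calibration uses 5,000 probes;
effect-recovery uses three pinned seeds at defaults; the end-to-end workflow
check runs 8,000 probes with the full 10,000/1,000 permutation settings.
These sizes are the package's own choice of a desk-scale demonstration; all
analyses scale linearly in probes.

## Known limitations

The dasen step is a faithful simplification (5th-percentile background
proxy), not a reimplementation of the published function. The isotonic PWF
is a step function where the original used a smooth monotone spline —
identical in spirit, slightly more conservative at the extremes of the
probe-count range. Region-level (DMR) analysis, surrogate-variable and
cell-composition adjustment, random-effects meta-analysis and IDAT parsing
are out of scope. Empirical P values have resolution 1/n_perm and can be
reported as 0; the fixed-threshold (primary) definition is undefined in
spirit for designs too small for any permutation to reach the threshold.
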