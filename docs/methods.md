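# Methods

## Risk-allele orientation and panels

A genetic risk score is only meaningful relative to a declared effect
allele, and minor alleles are population-dependent (the *DHCR7* rs12785878
minor allele is T in East and South Asian populations but G in Europeans),
so `grsdiet` never infers orientation from allele frequency. Each panel
entry names the risk allele and the other allele explicitly; genotype calls
("AG", "A/G") are counted against the risk allele, and numeric dosages carry
a declared coded allele and are flipped (d → 2−d) when coded on the other
allele. The shipped default panel — five vitamin D pathway SNPs and ten
obesity/type-2-diabetes SNPs — carries risk-allele orientations typical of
the GWAS literature but flags every entry `provisional: true`: the primary
sources for this panel report their exact orientations only in records we
do not redistribute, so the pipeline refuses to score the default panel
until the user either confirms the orientations in their own config or
passes `--accept-panel`.

Missing calls propagate: a subject with any missing call in a panel is
excluded from that panel's score (complete-case), and the exclusion list is
reported. Strand flipping, imputation and LD handling are out of scope; the
loader expects already-harmonized wide CSV/TSV genotype tables.

## Hardy–Weinberg screen

Per SNP, the risk-allele frequency p is estimated from the genotype counts
(n₂, n₁, n₀), expected counts are n·p², 2npq, n·q², and the Pearson
statistic is referred to χ² with one degree of freedom (one frequency
estimated from the data). No continuity correction is applied, and exact
tests are not implemented; with n ≈ 110 and MAF ≥ 0.2 the expected counts
are large enough that the asymptotic test holds its level (the suite checks
the empirical rejection rate at MAF 0.3 stays in [0.03, 0.07] at α = 0.05).
Monomorphic SNPs return χ² = 0, p = 1 by convention. Below MAF ≈ 0.1 at this
sample size the test becomes conservative; interpret accordingly.

## Scores and the median split

Scores are unweighted risk-allele counts (a per-SNP weight hook exists,
defaulting to 1). Dichotomization uses an integer threshold, the floor of
the sample median, under one of two conventions: `le_low` (score ≤ t → low;
the vitamin D panel default, e.g. ≤2 low / >2 high) and `lt_low`
(score < t → low; the metabolic panel default, e.g. <4 low / ≥4 high). The
two conventions differ only in which side the median score itself falls;
both appear in applied work, so both are explicit in the output manifest
rather than buried in code. Thresholds are computed on the analysis sample
(post-exclusion) and logged.

## Derived phenotypes and transforms

BMI, Friedewald LDL-c (rejected outright at TG ≥ 400 mg/dL rather than
silently extrapolated) and percent energy (Atwater 4/4/9 kcal/g, the carb
factor configurable) are exact arithmetic. Vitamin D status uses the IOM
bands resolved to half-open intervals — sufficient [20, ∞), insufficient
[12, 20), deficient (0, 12) — so every positive concentration receives
exactly one class; the published band wording ("≥12 ≤19") leaves (19, 20)
unassigned and contiguity is the conventional reading. Laboratory units are
taken as recorded (including assay-specific HbA1c ng/mL and insulin
nmlU/L); the validator treats them as opaque positive quantities.

The transformation gate applies a base-10 logarithm exactly when the
Shapiro–Wilk test rejects normality at α = 0.05, and records the decision
per variable. Base 10 (not e) is deliberate: status-group means of
log 25(OH)D near 1.2–1.3 against raw means of 16–19 ng/mL, and log BFP near
1.5–1.6 against raw 34–40%, are only consistent with log10. The gate is a
faithful reproduction of common practice in this literature, not an
endorsement; at n ≈ 110 it will leave mildly skewed variables untransformed
about 5% of the time by construction.

Tertiles are cut at the 1/3 and 2/3 sample quantiles (linear
interpolation); distinct values give groups differing by at most one
subject, and a constant variable collapses to T1 with a warning rather than
erroring.

## Regression models

All fits are OLS with intercept, two-sided t-tests, no robust standard
errors. The default adjustment set is age, BMI and location, with two
"where appropriate" rules applied mechanically and recorded in each fit:
BMI is removed when the outcome is an adiposity measure (BMI, WC, BFP — an
outcome should not be adjusted for itself or a near-copy), and total energy
intake is added only in diet-interaction models. Interaction models are
outcome ~ GRS + diet + GRS·diet + adjustment, with the GRS entering as the
binary median-split group by default (matching how such results are
presented) and as the raw score via an option, since either reading of
"GRS × dietary factor" is defensible. Diet enters on its transform-gate
scale; a raw-scale switch exists. P-values are nominal; the pipeline emits
a Bonferroni column alongside because the model grid
(2 panels × 4 diets × 11 outcomes) is large, but applies no correction
itself.

The summary-statistic ANOVA (SSB from group means around the grand mean,
SSW = Σ(nᵢ−1)sᵢ²) is algebraically identical to the raw-data decomposition,
which the suite verifies to machine precision; it exists so that published
n/mean/SD tables can be re-analyzed without raw data.

Tertile-stratified contrasts refit the adjusted low-vs-high comparison
within each intake tertile; any tertile×group cell with fewer than two
subjects is flagged and its p suppressed rather than reported from a
degenerate fit.

## Synthetic cohort generator

The generator emulates a cross-sectional cohort of adult women with the
margins of the motivating study population: 110 subjects; 15 independent
biallelic SNPs with dosages ~ Binomial(2, MAF), MAF defaulting to a uniform
0.3 placeholder because the cohort's allele frequencies are not published;
age truncated-normal 40.46 ± 9.38 on [25, 60]; 51% urban; carbohydrate
truncated-normal 233.08 ± 71.34 g/d on [121, 436], protein 77 ± 37, fat
59 ± 33, fiber 8.8 ± 4.3. Truncated normals are recentred (root-finding on
the analytic truncated mean) so the post-truncation mean hits the target
despite asymmetric bounds. Total energy is derived as
4·carb + 4·protein + 9·fat plus a small half-normal slack for unmodelled
items (fiber is counted within total carbohydrate), which keeps every
subject's macronutrient energy ≤ total energy and gives an expected intake
of ≈1790 kcal/d, matching the study's 1776 within 1%.

Planted effects are linear on the analysis scale: BMI gains
0.45 kg/m² per metabolic risk allele, log10 25(OH)D loses 0.022 per
metabolic risk allele, and log10 BFP gains
8×10⁻⁴ · (high vitamin D-GRS group) · (carbohydrate − 233.08 g). These
defaults were chosen to roughly reproduce the published low/high group-mean
gaps (≈1.85 kg/m² BMI, ≈0.08 log 25(OH)D, ≈0.07 log BFP in the top
carbohydrate tertile) given a metabolic-score spread of ≈2 alleles; the
true coefficients in the real cohort are not published, so the defaults are
labelled as reconstructions, not estimates. Outcomes flagged log-analyzed
are generated on the log10 scale and exponentiated, so the raw columns are
lognormal and the transformation gate re-discovers the transform.
Physiological guard clips (BMI 12–48, BFP 5–90%) sit beyond 3σ and
essentially never bind, keeping coefficient recovery unbiased.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, FFQ measurement error, assay error, or any
nonlinearity or heteroskedasticity. Passing tests therefore demonstrate
that the pipeline is correct and calibrated under its own modelling
assumptions — not that those assumptions hold in real cohorts.

## Calibration and recovery checks

The suite and the acceptance script verify, by simulation: type-I error of
the HWE screen (2000 equilibrium multinomial draws at n = 110, MAF 0.3) and
of the interaction test (1000 null cohorts at n = 110) within [0.03, 0.07]
at α = 0.05; 95% CI coverage of the planted interaction and both main-effect
coefficients within [0.92, 0.97] over 500 cohorts of n = 5000; and
monotonicity of interaction-test power in effect size and sample size.
Replicate counts were sized to keep Monte-Carlo error small relative to the
asserted bands (binomial SE ≈ 0.007 at 1000 reps, ≈ 0.010 at 500). Power at
n = 110 for a plausible interaction effect is reported by
`run_calibration`, not asserted — no external effect-size estimate exists
to anchor it.

## Determinism

Every stochastic component takes a single integer seed
(`numpy.random.default_rng`); identical seed and parameters give
bit-identical cohorts and byte-identical pipeline bundles. Sub-seeds for
replicate streams are drawn from a seeded generator and kept below 2³¹.

## Known limitations

- Unweighted scores only; no GWAS-weighted or cross-validated scores.
- No exact HWE test; the chi-square is conservative at low MAF.
- Complete-case panel scoring (per-SNP mean imputation exists as an option
  but is not the default); no genotype imputation.
- The adjustment-set rules are mechanical reproductions of stated practice;
  causal adequacy of that adjustment is not evaluated.
- The stratified contrasts inherit the multiple-testing exposure of the
  full model grid; the Bonferroni column is reported but not applied.
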