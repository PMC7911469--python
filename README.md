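# grsdiet

Genetic risk scores and gene–diet interaction analysis for small
nutrigenetic cohort studies.

`grsdiet` is aimed at epidemiologists and nutrition researchers who genotype
a candidate-SNP panel in a modest cohort (n ≈ 100–1000), build unweighted
genetic risk scores (GRS), and ask whether a dietary exposure modifies the
genetic association with an anthropometric or biochemical trait. It ships
the full path from raw genotype calls to stratified interaction tables,
plus a seeded synthetic-cohort generator so every stage is testable without
access to individual-level data.

## What it computes

**Risk scores.** For a panel of m SNPs with declared risk alleles, each
subject's score is the plain risk-allele count

&nbsp;&nbsp;GRS_i = Σ_j g_ij,&nbsp;&nbsp;g_ij ∈ {0, 1, 2},

so 0 ≤ GRS ≤ 2m. Two panels are built in: five vitamin D pathway SNPs
(*DHCR7*, *CYP2R1*, *CYP24A1*, *GC*, *CASR*) and ten metabolic-disease SNPs
(*FTO*×3, *TCF7L2*×2, *MC4R*×2, *KCNQ1*×2, *CDKN2A/B*). Scores are split at
the sample median into low/high genetic-risk groups; both boundary
conventions (median-low and median-high) are first-class. Risk-allele
orientation is explicit per SNP — minor alleles are population-dependent —
and the shipped orientations are flagged provisional until confirmed, which
the pipeline enforces.

**Quality control.** Each SNP is screened for Hardy–Weinberg equilibrium
with a 1-df Pearson goodness-of-fit chi-square (allele frequency estimated
from the genotype counts, no continuity correction).

**Phenotypes.** BMI = weight/height²; LDL-c by Friedewald
(TC − HDL-c − TG/5, valid for TG < 400 mg/dL); vitamin D status from serum
25(OH)D using the Institute of Medicine bands (sufficient ≥ 20 ng/mL,
insufficient 12–<20, deficient < 12); percent energy = 100·k·g/E with
Atwater factors k = 4/4/9 kcal/g. Variables failing a Shapiro–Wilk
normality test are log10-transformed before modelling.

**Models.** One-way ANOVA across vitamin D status groups (from raw data or
from published n/mean/SD summaries — the two routes agree to machine
precision); OLS of each outcome on the GRS group adjusted for age, BMI,
location and energy intake "where appropriate" (BMI is dropped when the
outcome is itself an adiposity measure); interaction models
outcome ~ GRS + diet + GRS·diet + covariates; and, for nominally significant
interactions, low-vs-high GRS contrasts within tertiles of intake.

**Synthetic cohorts.** `simulate_cohort` draws genotypes under HWE,
diet/covariates from truncated normals matched to the study population
(carbohydrate mean 233.08 g/d, SD 71.34, range 121–436; age 40.46 ± 9.38 on
[25, 60]; 51% urban), and plants configurable effects: a metabolic-GRS
effect on BMI and on log 25(OH)D, and a vitamin D-GRS × carbohydrate
interaction on log body-fat percentage. A truth record stores every planted
coefficient for recovery tests, and `run_calibration` estimates type-I error
and power of the interaction test over a parameter grid.

## Worked example

```bash
grsdiet simulate --n 110 --seed 7 --out-prefix demo
grsdiet report --genotypes demo_genotypes.csv --cohort demo_cohort.csv \
    --out-dir demo_bundle --accept-panel
```

`demo_bundle/` then contains `hwe_report.tsv` (15 rows; with this seed one
SNP, rs10163409, is flagged out of equilibrium — about what a 5% screen
should flag by chance in 15 tests), `grs.tsv` (two panels × 110 subjects),
`descriptives.tsv` (mean ± SD per vitamin D status group with ANOVA p per
row), `associations.tsv` (22 fits), `interactions.tsv` (88 fits with
nominal and Bonferroni p), one `stratified_*.tsv` per nominally significant
interaction, and `manifest.json`. The manifest records a vitamin D-GRS
median split at ≤3 (72 low / 38 high) and a metabolic split at <6
(45 low / 65 high). The planted carbohydrate interaction on body-fat
percentage is recovered in `interactions.tsv` (`vitamin_d / carb / bfp`,
p = 0.012), and its stratified table shows the low-vs-high contrast
concentrated in the top intake tertile (high-GRS mean BFP 40.8% vs 35.3%,
p = 0.059 at this sample size, against near-null gaps below).

In Python:

```python
from grsdiet import anova_from_summary, percent_energy

percent_energy(319, 1776, kcal_per_g=4)   # 71.85 — % energy from 319 g/d carbohydrate
anova_from_summary([(44, 43.8, 7.8), (44, 40.0, 10.9), (22, 34.3, 10.3)])
# {'F': 7.172, 'p': 0.00119, 'df': (2, 107)} — age gradient across status groups
```

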