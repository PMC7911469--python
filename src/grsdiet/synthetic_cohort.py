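"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a small cross-sectional cohort of adult women with
genotypes at 15 biallelic SNPs drawn under Hardy-Weinberg equilibrium,
dietary intake and covariate distributions matched to the study population
(e.g. carbohydrate ~ truncated normal, mean 233.08 g/d, SD 71.34, range
121-436), and planted genetic effects:

* a metabolic-GRS main effect on BMI (per risk allele, kg/m^2) and on
  log10 25(OH)D (per risk allele);
* a vitamin D-GRS x carbohydrate interaction on log10 body fat percentage,
  entering through the binary median-split GRS group times mean-centered
  carbohydrate grams.

Outcomes flagged as log-analyzed in the real study (25(OH)D, BFP) are
generated on the log10 scale and exponentiated into the cohort table, so the
raw columns are lognormal and the normality gate re-discovers the transform.
Every planted coefficient is returned in a truth record for recovery tests.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from grsdiet.phenotypes import validate_cohort
from grsdiet.scoring import compute_grs, dichotomize, median_threshold
from grsdiet.snp_panel import GenotypeMatrix, SnpDefinition, default_panel


@dataclass
class SimulationParams:
    """Generator settings; defaults reproduce the study-population margins."""

    n_subjects: int = 110
    maf_per_snp: tuple[float, ...] = (0.3,) * 15  # per-SNP risk-allele freq

    # planted effects
    beta_metabolic_on_bmi: float = 0.45  # kg/m^2 per metabolic risk allele
    beta_metabolic_on_log_vitd: float = -0.022  # log10 ng/mL per risk allele
    beta_interaction_vitdgrs_carb_on_log_bfp: float = 8e-4  # log10 % per g/d

    # diet and covariates
    carb_mean: float = 233.08  # g/d
    carb_sd: float = 71.34
    carb_range: tuple[float, float] = (121.0, 436.0)
    # total energy is derived from the macronutrient grams (4/4/9 kcal/g)
    # plus a nonnegative slack for unmodelled items; the default macro means
    # imply ~1776 kcal/d in expectation, matching the study population
    energy_slack_sd: float = 25.0  # kcal/d, half-normal
    protein_mean: float = 77.0  # g/d
    protein_sd: float = 37.0
    fat_mean: float = 59.0  # g/d
    fat_sd: float = 33.0
    fiber_mean: float = 8.8  # g/d
    fiber_sd: float = 4.3
    age_mean: float = 40.46  # years
    age_sd: float = 9.38
    age_range: tuple[float, float] = (25.0, 60.0)
    urban_fraction: float = 0.51

    # outcome baselines and noise SDs (noise on the analysis scale)
    bmi_baseline: float = 22.5  # kg/m^2 before genetic effects
    bmi_noise_sd: float = 4.0
    log_vitd_baseline: float = 1.38  # log10 ng/mL before genetic effects
    log_vitd_noise_sd: float = 0.19
    log_bfp_baseline: float = 1.545  # log10 percent
    log_bfp_noise_sd: float = 0.085
    height_mean: float = 1.53  # m
    height_sd: float = 0.05
    wc_mean: float = 83.9  # cm
    wc_sd: float = 10.4
    glucose_mean: float = 92.0  # mg/dL
    glucose_sd: float = 18.0
    hba1c_mean: float = 640.0  # ng/mL (assay units as recorded)
    hba1c_sd: float = 550.0
    insulin_mean: float = 32000.0  # nmlU/L (assay units as recorded)
    insulin_sd: float = 25000.0
    tc_mean: float = 208.0  # mg/dL
    tc_sd: float = 44.0
    hdl_mean: float = 59.0  # mg/dL
    hdl_sd: float = 10.0
    tg_mean: float = 98.0  # mg/dL
    tg_sd: float = 43.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(self.maf_per_snp) != 15:
            raise ValueError("maf_per_snp must hold 15 frequencies")
        for m in self.maf_per_snp:
            if not 0.0 < m < 1.0:
                raise ValueError(f"allele frequency {m} outside (0, 1)")
        for name in (
            "carb_sd",
            "energy_slack_sd",
            "age_sd",
            "bmi_noise_sd",
            "log_vitd_noise_sd",
            "log_bfp_noise_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.carb_range, self.age_range):
            if lo >= hi:
                raise ValueError("truncation bounds must be ordered")
        if not 0.0 < self.urban_fraction < 1.0:
            raise ValueError("urban_fraction must lie in (0, 1)")


@functools.lru_cache(maxsize=64)
def _recentred_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals ``mean``.

    Truncation at asymmetric bounds shifts the mean of a clipped normal, so
    the location is recentred by root-finding on the analytic truncated-normal
    mean.
    """
    from scipy import optimize, stats as sps

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(sps.truncnorm.mean(a, b, loc=mu, scale=sd))

    if abs(trunc_mean(mean) - mean) <= 1e-9:
        return mean
    return float(
        optimize.brentq(
            lambda m: trunc_mean(m) - mean, lo - 6 * sd, hi + 6 * sd, xtol=1e-8
        )
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal with post-truncation mean ``mean``."""
    mean = _recentred_location(mean, sd, lo, hi)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_genotypes(
    params: SimulationParams,
    snps: list[SnpDefinition] | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw risk-allele dosages ~ Binomial(2, freq) per SNP, independent subjects."""
    params.validate()
    if snps is None:
        snps = default_panel()
    if len(snps) != len(params.maf_per_snp):
        raise ValueError("one allele frequency per SNP is required")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dosage = np.column_stack(
        [
            rng.binomial(2, maf, size=params.n_subjects)
            for maf in params.maf_per_snp
        ]
    )
    ids = [f"S{i + 1:04d}" for i in range(params.n_subjects)]
    return GenotypeMatrix(subject_ids=ids, snps=snps, dosage=dosage)


def simulate_cohort(
    params: SimulationParams | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """Generate a full cohort: genotypes, phenotypes, diet, and a truth record.

    Outcome construction (analysis scale):

    * BMI = baseline + b_met_bmi * metabolic_score + N(0, bmi_noise_sd)
    * log10 25(OH)D = baseline + b_met_vitd * metabolic_score + noise
      (b_met_vitd is negative: risk alleles lower vitamin D status)
    * log10 BFP = baseline + b_bmi_bfp * (BMI - 25) + b_int * high_vitd_group
      * (carb - carb_mean) + noise, where high_vitd_group is the
      median-split vitamin D-GRS indicator

    Weight is back-computed from BMI and height so the derived-column
    validator reproduces the planted BMI exactly.
    """
    if params is None:
        params = SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    genotypes = simulate_genotypes(params, rng=rng)
    met_score, _ = compute_grs(genotypes, "metabolic")
    vitd_score, _ = compute_grs(genotypes, "vitamin_d")
    vitd_thresh = median_threshold(vitd_score)
    vitd_group = dichotomize(vitd_score, vitd_thresh, "le_low")["group"]
    high = (vitd_group == "high").to_numpy(dtype=float)

    age = _truncated_normal(
        rng, params.age_mean, params.age_sd, *params.age_range, n
    )
    location = np.where(
        rng.random(n) < params.urban_fraction, "urban", "rural"
    )
    carb = _truncated_normal(
        rng, params.carb_mean, params.carb_sd, *params.carb_range, n
    )
    protein = _truncated_normal(
        rng, params.protein_mean, params.protein_sd, 15.0, 250.0, n
    )
    fat = _truncated_normal(rng, params.fat_mean, params.fat_sd, 10.0, 220.0, n)
    fiber = _truncated_normal(rng, params.fiber_mean, params.fiber_sd, 1.0, 35.0, n)
    # fiber is counted inside total carbohydrate, so it adds no extra energy
    energy = (
        4.0 * carb
        + 4.0 * protein
        + 9.0 * fat
        + np.abs(rng.normal(0.0, params.energy_slack_sd, n))
    )

    met = met_score.to_numpy(dtype=float)
    bmi_vals = (
        params.bmi_baseline
        + params.beta_metabolic_on_bmi * met
        + rng.normal(0.0, params.bmi_noise_sd, n)
    )
    bmi_vals = np.clip(bmi_vals, 12.0, 48.0)  # physiological guard, ~never binds
    log_vitd = (
        params.log_vitd_baseline
        + params.beta_metabolic_on_log_vitd * met
        + rng.normal(0.0, params.log_vitd_noise_sd, n)
    )
    beta_bmi_on_log_bfp = 0.012  # adiposity coupling, log10 % per kg/m^2
    log_bfp = (
        params.log_bfp_baseline
        + beta_bmi_on_log_bfp * (bmi_vals - 25.0)
        + params.beta_interaction_vitdgrs_carb_on_log_bfp
        * high
        * (carb - params.carb_mean)
        + rng.normal(0.0, params.log_bfp_noise_sd, n)
    )
    bfp = np.clip(10 ** log_bfp, 5.0, 90.0)  # validator guard, ~never binds

    height = _truncated_normal(
        rng, params.height_mean, params.height_sd, 1.35, 1.75, n
    )
    weight = bmi_vals * height**2
    wc = _truncated_normal(rng, params.wc_mean, params.wc_sd, 55.0, 130.0, n)
    glucose = _truncated_normal(
        rng, params.glucose_mean, params.glucose_sd, 55.0, 250.0, n
    )
    hba1c = np.exp(
        rng.normal(np.log(params.hba1c_mean) - 0.3, 0.75, n)
    )  # heavy-tailed assay values
    insulin = np.exp(rng.normal(np.log(params.insulin_mean) - 0.25, 0.7, n))
    tc = _truncated_normal(rng, params.tc_mean, params.tc_sd, 110.0, 360.0, n)
    hdl = _truncated_normal(rng, params.hdl_mean, params.hdl_sd, 30.0, 95.0, n)
    tg = _truncated_normal(rng, params.tg_mean, params.tg_sd, 35.0, 380.0, n)

    cohort = pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "age": age,
            "location": location,
            "weight": weight,
            "height": height,
            "wc": wc,
            "bfp": bfp,
            "vitd": 10 ** log_vitd,
            "glucose": glucose,
            "hba1c": hba1c,
            "insulin": insulin,
            "tc": tc,
            "hdl": hdl,
            "tg": tg,
            "energy": energy,
            "carb": carb,
            "protein": protein,
            "fat": fat,
            "fiber": fiber,
        }
    )
    cohort = validate_cohort(cohort)

    truth = {
        "seed": params.seed,
        "n_subjects": n,
        "beta_metabolic_on_bmi": params.beta_metabolic_on_bmi,
        "beta_metabolic_on_log_vitd": params.beta_metabolic_on_log_vitd,
        "beta_interaction_vitdgrs_carb_on_log_bfp": (
            params.beta_interaction_vitdgrs_carb_on_log_bfp
        ),
        "beta_bmi_on_log_bfp": beta_bmi_on_log_bfp,
        "vitd_grs_threshold": vitd_thresh,
        "carb_center": params.carb_mean,
        "log_vitd_baseline": params.log_vitd_baseline,
        "log_bfp_baseline": params.log_bfp_baseline,
        "bmi_baseline": params.bmi_baseline,
    }
    return cohort, genotypes, truth


def _interaction_pvalue(params: SimulationParams) -> float:
    """Fit the planted interaction model on one simulated cohort; return its p."""
    from grsdiet.models import fit_interaction

    cohort, genotypes, truth = simulate_cohort(params)
    vitd_score, _ = compute_grs(genotypes, "vitamin_d")
    group = dichotomize(vitd_score, truth["vitd_grs_threshold"], "le_low")["group"]
    fitted = cohort.copy()
    fitted["log_bfp"] = np.log10(fitted["bfp"])
    fitted["carb_c"] = fitted["carb"] - truth["carb_center"]
    fit = fit_interaction(
        fitted,
        group.to_numpy(),
        diet="carb_c",
        outcome="log_bfp",
        transformed=True,
    )
    return float(fit.term("grs:diet")["p"])


def run_calibration(
    effect_grid: list[float],
    n_grid: list[int],
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    base_params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Empirical rejection rate of the interaction test over a parameter grid.

    Each grid cell simulates ``n_reps`` cohorts, refits the interaction
    model, and reports the fraction of p-values below ``alpha`` with its
    Monte-Carlo standard error.  A zero effect estimates the type-I error;
    nonzero effects estimate power.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    base = base_params or SimulationParams()
    rows = []
    seed_stream = np.random.default_rng(seed)
    for beta in effect_grid:
        for n in n_grid:
            rejections = 0
            for _ in range(n_reps):
                p = _interaction_pvalue(
                    SimulationParams(
                        **{
                            **asdict(base),
                            "n_subjects": n,
                            "beta_interaction_vitdgrs_carb_on_log_bfp": beta,
                            "seed": int(seed_stream.integers(0, 2**31 - 1)),
                        }
                    )
                )
                rejections += p < alpha
            rate = rejections / n_reps
            rows.append(
                {
                    "beta_interaction": beta,
                    "n_subjects": n,
                    "n_reps": n_reps,
                    "alpha": alpha,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
                }
            )
    return pd.DataFrame(rows)
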