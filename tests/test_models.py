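"""ANOVA routes, adjusted association fits, interaction and stratified models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from grsdiet.models import (
    ModelSpecificationError,
    anova_from_summary,
    anova_oneway,
    fit_association,
    fit_interaction,
    stratified_contrast,
)
from grsdiet.phenotypes import assign_tertiles
from grsdiet.scoring import compute_grs, dichotomize
from grsdiet.synthetic_cohort import SimulationParams, simulate_cohort


def summarize(groups):
    return [(len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups]


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        res = anova_oneway([g, g + 0.0])
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.6, 1, 12)
        res = anova_oneway([a, b])
        t, p_t = stats.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p_t, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ModelSpecificationError):
            anova_oneway([np.array([1.0]), np.array([1.0, 2.0])])

    def test_age_gradient_across_vitamin_d_groups(self):
        """Published-style (n, mean, sd) age summaries give p ~ 0.001."""
        res = anova_from_summary([(44, 43.8, 7.8), (44, 40.0, 10.9), (22, 34.3, 10.3)])
        assert res["df"] == (2, 107)
        assert res["F"] == pytest.approx(7.17, abs=0.01)
        assert round(res["p"], 3) == 0.001

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=100)
    def test_summary_route_equals_raw_route(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [
            rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3), rng.integers(2, 30))
            for _ in range(k)
        ]
        raw = anova_oneway(groups)
        summ = anova_from_summary(summarize(groups))
        assert summ["F"] == pytest.approx(raw["F"], rel=1e-9, abs=1e-12)
        assert summ["p"] == pytest.approx(raw["p"], rel=1e-9, abs=1e-12)


@pytest.fixture(scope="module")
def fitted_cohort():
    cohort, genotypes, truth = simulate_cohort(SimulationParams(seed=21))
    vitd_score, _ = compute_grs(genotypes, "vitamin_d")
    group = dichotomize(vitd_score, truth["vitd_grs_threshold"], "le_low")["group"]
    cohort = cohort.copy()
    cohort["log_bfp"] = np.log10(cohort["bfp"])
    cohort["log_vitd"] = np.log10(cohort["vitd"])
    return cohort, group.to_numpy(), truth


class TestFitAssociation:
    def test_unadjusted_binary_equals_pooled_t_test(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        fit = fit_association(cohort, group, "log_vitd", adjustment=[])
        a = cohort.loc[group == "high", "log_vitd"]
        b = cohort.loc[group == "low", "log_vitd"]
        _, p_t = stats.ttest_ind(a, b)
        assert fit.term("grs")["p"] == pytest.approx(p_t, rel=1e-9)
        assert fit.term("grs")["estimate"] == pytest.approx(a.mean() - b.mean())

    def test_outcome_identical_to_covariate_fits_perfectly(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        cohort2 = cohort.copy()
        cohort2["age_copy"] = cohort2["age"]
        fit = fit_association(cohort2, group, "age_copy", adjustment=["age"])
        assert fit.extras["r_squared"] == pytest.approx(1.0)

    def test_bmi_dropped_for_adiposity_outcomes(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        for outcome in ("bmi", "wc", "bfp", "log_bfp"):
            fit = fit_association(cohort, group, outcome)
            assert "bmi" not in fit.adjustment_set
        fit = fit_association(cohort, group, "glucose")
        assert "bmi" in fit.adjustment_set

    def test_constant_group_rejected(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        with pytest.raises(ModelSpecificationError):
            fit_association(cohort, np.zeros(len(cohort)), "glucose")

    def test_planted_main_effect_recovered_at_large_n(self):
        params = SimulationParams(seed=31, n_subjects=5000)
        cohort, genotypes, truth = simulate_cohort(params)
        met_score, _ = compute_grs(genotypes, "metabolic")
        cohort = cohort.copy()
        cohort["met_score"] = met_score.to_numpy(dtype=float)
        cohort["log_vitd"] = np.log10(cohort["vitd"])
        for outcome, beta in (
            ("bmi", truth["beta_metabolic_on_bmi"]),
            ("log_vitd", truth["beta_metabolic_on_log_vitd"]),
        ):
            fit = fit_association(
                cohort, cohort["met_score"], outcome, adjustment=[]
            )
            term = fit.term("grs")
            assert abs(term["estimate"] - beta) < 3 * term["se"]


class TestFitInteraction:
    def test_planted_interaction_recovered_at_large_n(self):
        beta = 8e-4
        params = SimulationParams(
            seed=41, n_subjects=5000, beta_interaction_vitdgrs_carb_on_log_bfp=beta
        )
        cohort, genotypes, truth = simulate_cohort(params)
        vitd_score, _ = compute_grs(genotypes, "vitamin_d")
        group = dichotomize(vitd_score, truth["vitd_grs_threshold"], "le_low")["group"]
        cohort = cohort.copy()
        cohort["log_bfp"] = np.log10(cohort["bfp"])
        cohort["carb_c"] = cohort["carb"] - truth["carb_center"]
        fit = fit_interaction(
            cohort, group.to_numpy(), diet="carb_c", outcome="log_bfp"
        )
        term = fit.term("grs:diet")
        assert abs(term["estimate"] - beta) < 3 * term["se"]

    def test_constant_diet_rejected(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        cohort2 = cohort.copy()
        cohort2["flat"] = 1.0
        with pytest.raises(ModelSpecificationError):
            fit_interaction(cohort2, group, diet="flat", outcome="glucose")

    def test_energy_in_default_interaction_adjustment(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        fit = fit_interaction(cohort, group, diet="carb", outcome="glucose")
        assert "energy" in fit.adjustment_set


class TestStratifiedContrast:
    def test_structure_three_tertiles_two_groups(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        tert, _ = assign_tertiles(cohort["carb"].reset_index(drop=True))
        table = stratified_contrast(
            cohort.reset_index(drop=True), group, tert, "log_bfp"
        )
        assert table["tertile"].tolist() == ["T1", "T2", "T3"]
        assert (table["low_n"] + table["high_n"]).sum() == len(cohort)

    def test_single_subject_cell_flagged(self, fitted_cohort):
        cohort, group, _ = fitted_cohort
        g = np.array(["low"] * len(cohort), dtype=object)
        g[0] = "high"
        tert, _ = assign_tertiles(cohort["carb"].reset_index(drop=True))
        table = stratified_contrast(
            cohort.reset_index(drop=True), g, tert, "log_bfp"
        )
        flagged = table.loc[table["high_n"] < 2]
        assert flagged["flagged"].all()
        assert flagged["p_value"].isna().all()

    def test_planted_interaction_concentrates_in_top_tertile(self):
        """With a strong planted effect the high-GRS excess is largest in T3."""
        params = SimulationParams(
            seed=51, n_subjects=5000, beta_interaction_vitdgrs_carb_on_log_bfp=2e-3
        )
        cohort, genotypes, truth = simulate_cohort(params)
        vitd_score, _ = compute_grs(genotypes, "vitamin_d")
        group = dichotomize(vitd_score, truth["vitd_grs_threshold"], "le_low")["group"]
        cohort = cohort.copy()
        cohort["log_bfp"] = np.log10(cohort["bfp"])
        tert, _ = assign_tertiles(cohort["carb"].reset_index(drop=True))
        table = stratified_contrast(
            cohort.reset_index(drop=True), group.to_numpy(), tert, "log_bfp"
        ).set_index("tertile")
        gaps = table["high_mean"] - table["low_mean"]
        assert gaps["T3"] > gaps["T1"]
        assert table.loc["T3", "p_value"] < 0.05
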