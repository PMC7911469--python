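"""Derived phenotypes, vitamin D status classes, transforms, and validation.

Covers the cohort-table side of the analysis: BMI from weight/height,
LDL cholesterol via the Friedewald equation, vitamin D status from serum
25(OH)D using the Institute of Medicine bands, percent of energy supplied by
a macronutrient, Shapiro-Wilk-gated base-10 log transformation, and tertile
assignment for dietary stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Atwater energy-conversion factors, kcal per gram
KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0, "fiber": 2.0}

#: IOM serum 25(OH)D cutpoints, ng/mL
VITD_SUFFICIENT_NGML = 20.0
VITD_DEFICIENT_NGML = 12.0

VITD_CLASSES = ("sufficient", "insufficient", "deficient")

#: columns a cohort table must provide (derived columns are added by the validator)
REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "age",
    "location",
    "weight",
    "height",
    "wc",
    "bfp",
    "vitd",
    "glucose",
    "hba1c",
    "insulin",
    "tc",
    "hdl",
    "tg",
    "energy",
    "carb",
    "protein",
    "fat",
    "fiber",
)


class CohortValidationError(ValueError):
    """A cohort table violated the schema or a physiological-range invariant."""


class DegenerateCutpointWarning(UserWarning):
    """Tertile cutpoints collapsed because the values are (nearly) constant."""


def bmi(weight: float | np.ndarray, height: float | np.ndarray) -> float | np.ndarray:
    """Body mass index, kg/m^2: weight (kg) over squared height (m)."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise CohortValidationError("weight and height must be positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(
    tc: float | np.ndarray, hdl: float | np.ndarray, tg: float | np.ndarray
) -> float | np.ndarray:
    """LDL-c (mg/dL) by the Friedewald equation: TC - HDL-c - TG/5.

    Valid only for triglycerides below 400 mg/dL; higher values raise.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise CohortValidationError("lipid concentrations must be nonnegative")
    if np.any(tg >= 400):
        raise CohortValidationError(
            "Friedewald equation is invalid at TG >= 400 mg/dL"
        )
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out


def classify_vitd(vitd: float) -> str:
    """Vitamin D status from serum 25(OH)D (ng/mL), IOM bands.

    sufficient >= 20; insufficient in [12, 20); deficient < 12.  The bands
    are half-open so every positive concentration gets exactly one class.
    """
    v = float(vitd)
    if not np.isfinite(v) or v <= 0:
        raise CohortValidationError(f"25(OH)D must be positive, got {vitd!r}")
    if v >= VITD_SUFFICIENT_NGML:
        return "sufficient"
    if v >= VITD_DEFICIENT_NGML:
        return "insufficient"
    return "deficient"


def percent_energy(
    macronutrient_g: float, energy_kcal: float, kcal_per_g: float = 4.0
) -> float:
    """Percent of daily energy supplied by a macronutrient.

    100 * kcal_per_g * grams / energy; kcal_per_g is 4 for carbohydrate and
    protein, 9 for fat (Atwater factors).
    """
    if energy_kcal <= 0:
        raise CohortValidationError("total energy intake must be positive")
    if macronutrient_g < 0:
        raise CohortValidationError("macronutrient grams must be nonnegative")
    return 100.0 * kcal_per_g * macronutrient_g / energy_kcal


@dataclass(frozen=True)
class TransformRecord:
    """Outcome of the normality gate for one variable."""

    variable: str
    shapiro_p: float
    transformed: bool
    transform: str  # "log10" | "identity"


def log_transform_if_nonnormal(
    values: pd.Series | np.ndarray,
    alpha: float = 0.05,
    variable: str = "",
) -> tuple[np.ndarray, TransformRecord]:
    """Base-10 log transform applied only when Shapiro-Wilk rejects normality.

    Returns the (possibly transformed) values and a record of the decision.
    Transformation of nonpositive values is an error naming the offenders.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 3:
        raise CohortValidationError(
            f"{variable or 'variable'}: need >=3 observations for a normality test"
        )
    _, p = stats.shapiro(finite)
    if p >= alpha:
        return arr, TransformRecord(variable, float(p), False, "identity")
    bad = np.where(arr <= 0)[0]
    if bad.size:
        raise CohortValidationError(
            f"{variable or 'variable'}: cannot log-transform nonpositive values "
            f"at rows {bad.tolist()[:10]}"
        )
    return np.log10(arr), TransformRecord(variable, float(p), True, "log10")


def assign_tertiles(
    values: pd.Series | np.ndarray,
) -> tuple[pd.Series, pd.DataFrame]:
    """Split a variable into tertiles T1 < T2 < T3 at the 1/3 and 2/3 quantiles.

    Returns (labels, summary) where summary holds per-tertile n, mean and SD.
    With distinct values the groups differ in size by at most one; constant
    input collapses into T1 with a :class:`DegenerateCutpointWarning`.
    """
    s = pd.Series(values) if not isinstance(values, pd.Series) else values
    if len(s) < 3:
        raise CohortValidationError("tertile assignment needs at least 3 subjects")
    q1, q2 = np.quantile(s.to_numpy(dtype=float), [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn(
            "degenerate tertile cutpoints (values nearly constant); "
            "all subjects assigned T1",
            DegenerateCutpointWarning,
            stacklevel=2,
        )
        labels = pd.Series("T1", index=s.index, name="tertile")
    else:
        labels = pd.Series(
            np.where(s <= q1, "T1", np.where(s <= q2, "T2", "T3")),
            index=s.index,
            name="tertile",
        )
    summary = (
        pd.DataFrame({"value": s, "tertile": labels})
        .groupby("tertile")["value"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    summary["cut_low"] = q1
    summary["cut_high"] = q2
    return labels, summary


def validate_cohort(
    df: pd.DataFrame,
    age_bounds: tuple[float, float] = (25.0, 60.0),
    percent_energy_warn: float = 105.0,
) -> pd.DataFrame:
    """Validate a cohort table and append derived columns.

    Checks the header contract, positivity of concentrations and intakes,
    the age window, BFP in (0, 100) and the location labels; adds ``bmi``,
    ``ldl`` (Friedewald, unless already supplied), ``vitd_class`` and
    ``pct_energy_{carb,protein,fat}``.  Returns a copy; raises
    :class:`CohortValidationError` listing every failed check.
    """
    problems: list[str] = []
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table lacks column(s): {missing}")
    out = df.copy()

    if out["subject_id"].duplicated().any():
        problems.append("duplicate subject_id values")
    bad_loc = set(out["location"].unique()) - {"urban", "rural"}
    if bad_loc:
        problems.append(f"location labels outside {{urban,rural}}: {sorted(bad_loc)}")

    lo, hi = age_bounds
    n_bad_age = int(((out["age"] < lo) | (out["age"] > hi)).sum())
    if n_bad_age:
        problems.append(f"{n_bad_age} subjects outside age bounds [{lo}, {hi}]")

    positive_cols = (
        "weight height wc vitd glucose hba1c insulin tc hdl tg "
        "energy carb protein fat fiber"
    ).split()
    for col in positive_cols:
        n_bad = int((pd.to_numeric(out[col], errors="coerce") <= 0).sum())
        n_nan = int(pd.to_numeric(out[col], errors="coerce").isna().sum())
        if n_bad or n_nan:
            problems.append(f"{col}: {n_bad + n_nan} nonpositive or missing values")

    n_bad_bfp = int(((out["bfp"] <= 0) | (out["bfp"] >= 100)).sum())
    if n_bad_bfp:
        problems.append(f"bfp: {n_bad_bfp} values outside (0, 100)")

    if problems:
        raise CohortValidationError("; ".join(problems))

    out["bmi"] = bmi(out["weight"].to_numpy(), out["height"].to_numpy())
    if "ldl" not in out.columns:
        out["ldl"] = friedewald_ldl(
            out["tc"].to_numpy(), out["hdl"].to_numpy(), out["tg"].to_numpy()
        )
    out["vitd_class"] = [classify_vitd(v) for v in out["vitd"]]
    for macro in ("carb", "protein", "fat"):
        out[f"pct_energy_{macro}"] = [
            percent_energy(g, e, KCAL_PER_G[macro])
            for g, e in zip(out[macro], out["energy"])
        ]
    total_pct = (
        out["pct_energy_carb"] + out["pct_energy_protein"] + out["pct_energy_fat"]
    )
    n_over = int((total_pct > percent_energy_warn).sum())
    if n_over:
        warnings.warn(
            f"{n_over} subjects report macronutrient energy above "
            f"{percent_energy_warn}% of total intake",
            UserWarning,
            stacklevel=2,
        )
    return out


def descriptive_table(
    cohort: pd.DataFrame,
    by: str = "vitd_class",
    variables: tuple[str, ...] = (
        "age",
        "bmi",
        "wc",
        "bfp",
        "glucose",
        "hba1c",
        "insulin",
        "tc",
        "hdl",
        "ldl",
        "tg",
        "energy",
        "carb",
        "protein",
        "fat",
        "fiber",
    ),
) -> pd.DataFrame:
    """Raw-scale mean +/- SD per group with a one-way ANOVA p-value per row."""
    from grsdiet.models import anova_oneway

    groups = [g for g in VITD_CLASSES if g in set(cohort[by])] or sorted(
        set(cohort[by])
    )
    rows = []
    for var in variables:
        row: dict[str, object] = {"variable": var}
        samples = []
        for g in groups:
            vals = cohort.loc[cohort[by] == g, var].to_numpy(dtype=float)
            samples.append(vals)
            row[f"{g}_n"] = len(vals)
            row[f"{g}_mean"] = float(np.mean(vals))
            row[f"{g}_sd"] = float(np.std(vals, ddof=1))
        if len(samples) >= 2 and all(len(v) >= 2 for v in samples):
            fit = anova_oneway(samples)
            row["p_value"] = fit["p"]
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
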