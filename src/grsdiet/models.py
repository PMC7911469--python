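"""Regression and ANOVA models for GRS association and gene-diet interaction.

Three families of fits:

* one-way ANOVA across vitamin D status groups, from raw data or from
  published (n, mean, SD) summaries — the two routes are algebraically
  identical;
* covariate-adjusted ordinary least squares of an outcome on the low/high
  GRS group (or the raw score), adjusted for age, BMI, location and total
  energy intake "wherever appropriate": BMI is dropped from the adjustment
  set when the outcome is itself an adiposity measure, and energy intake is
  included only when diet is in the model;
* GRS x diet interaction models (outcome ~ GRS + diet + GRS:diet +
  adjustment) with tertile-stratified low-vs-high contrasts to localize a
  significant interaction.

All tests are two-sided; p-values are nominal, with an optional Bonferroni
column in the pipeline outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: outcomes for which BMI is removed from the adjustment set
ADIPOSITY_OUTCOMES = frozenset({"bmi", "wc", "bfp"})

DEFAULT_ADJUSTMENT = ("age", "bmi", "location")


class ModelSpecificationError(ValueError):
    """Invalid or degenerate model specification (singular design, bad data)."""


@dataclass
class ModelFit:
    """A fitted model: per-term coefficient table plus bookkeeping."""

    outcome: str
    transformed: bool
    model_kind: str  # "association" | "interaction" | "anova"
    terms: pd.DataFrame  # columns: term, estimate, se, t, p
    adjustment_set: list[str]
    n_used: int
    extras: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        match = self.terms[self.terms["term"] == name]
        if match.empty:
            raise KeyError(f"term {name!r} not in fit of {self.outcome}")
        return match.iloc[0]


def anova_oneway(values_by_group: Sequence[np.ndarray]) -> dict:
    """Classical one-way ANOVA: F with (k-1, N-k) degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ModelSpecificationError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ModelSpecificationError("every ANOVA group needs n >= 2")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    return {"F": float(f), "p": float(p), "df": (k - 1, n_total - k)}


def anova_from_summary(
    groups: Sequence[tuple[int, float, float]],
) -> dict:
    """One-way ANOVA reconstructed from per-group (n, mean, sd) summaries.

    Between-group sum of squares comes from the group means around the grand
    mean; within-group from (n-1)*sd^2.  Identical to :func:`anova_oneway`
    applied to any raw data with these summaries.
    """
    if len(groups) < 2:
        raise ModelSpecificationError("ANOVA needs at least two groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ModelSpecificationError("every ANOVA group needs n >= 2")
    if np.any(sds < 0):
        raise ModelSpecificationError("group SDs must be nonnegative")
    n_total = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return {"F": float(f), "p": p, "df": (int(df_b), int(df_w))}


def _resolve_adjustment(
    outcome: str, adjustment: Sequence[str] | None, with_diet: bool
) -> list[str]:
    if adjustment is None:
        adjustment = list(DEFAULT_ADJUSTMENT)
        if with_diet:
            adjustment.append("energy")
    adjustment = list(adjustment)
    base = outcome.lower().removeprefix("log_")
    if base in ADIPOSITY_OUTCOMES and "bmi" in adjustment:
        adjustment.remove("bmi")
    if outcome in adjustment:
        adjustment.remove(outcome)
    return adjustment


def _design_column(cohort: pd.DataFrame, name: str) -> np.ndarray:
    col = cohort[name]
    if name == "location" or col.dtype == object:
        levels = sorted(col.unique())
        if len(levels) == 1:
            raise ModelSpecificationError(f"covariate {name!r} has a single level")
        if len(levels) > 2:
            raise ModelSpecificationError(
                f"covariate {name!r} has >2 levels; recode before fitting"
            )
        return (col == levels[1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def _grs_numeric(grs_group: pd.Series | np.ndarray) -> np.ndarray:
    g = pd.Series(grs_group)
    if g.dtype == object:
        bad = set(g.unique()) - {"low", "high"}
        if bad:
            raise ModelSpecificationError(f"unknown GRS group labels: {sorted(bad)}")
        return (g == "high").to_numpy(dtype=float)
    return g.to_numpy(dtype=float)


def _ols(
    y: np.ndarray, X: pd.DataFrame, outcome: str
) -> sm.regression.linear_model.RegressionResultsWrapper:
    n, p = X.shape
    if n < p + 1:
        raise ModelSpecificationError(
            f"{outcome}: {n} observations cannot support {p} parameters"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        zero_var = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
        raise ModelSpecificationError(
            f"{outcome}: singular design"
            + (f" (constant predictor(s): {zero_var})" if zero_var else "")
        )
    return sm.OLS(y, X).fit()


def _terms_frame(res, names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": names,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )


def fit_association(
    cohort: pd.DataFrame,
    grs_group: pd.Series | np.ndarray,
    outcome: str,
    adjustment: Sequence[str] | None = None,
    transformed: bool = False,
) -> ModelFit:
    """OLS of an outcome on the GRS group (binary low/high or raw score).

    ``adjustment=None`` applies the default set (age, BMI, location), with
    BMI removed automatically for adiposity outcomes.  Pass ``adjustment=[]``
    for an unadjusted fit.
    """
    adj = _resolve_adjustment(outcome, adjustment, with_diet=False)
    g = _grs_numeric(grs_group)
    y = cohort[outcome].to_numpy(dtype=float)
    X = pd.DataFrame({"const": np.ones(len(y)), "grs": g})
    for name in adj:
        X[name] = _design_column(cohort, name)
    if X["grs"].nunique() <= 1:
        raise ModelSpecificationError(f"{outcome}: GRS group is constant")
    res = _ols(y, X, outcome)
    return ModelFit(
        outcome=outcome,
        transformed=transformed,
        model_kind="association",
        terms=_terms_frame(res, list(X.columns)),
        adjustment_set=adj,
        n_used=int(res.nobs),
        extras={"r_squared": float(res.rsquared)},
    )


def fit_interaction(
    cohort: pd.DataFrame,
    grs_group: pd.Series | np.ndarray,
    diet: str,
    outcome: str,
    adjustment: Sequence[str] | None = None,
    transformed: bool = False,
) -> ModelFit:
    """Gene-diet interaction model: outcome ~ GRS + diet + GRS:diet + adjustment.

    The reported term of interest is ``grs:diet``.  Diet enters on whatever
    scale the ``diet`` column carries (log-transform upstream if the
    normality gate flagged it).
    """
    adj = _resolve_adjustment(outcome, adjustment, with_diet=True)
    adj = [a for a in adj if a != diet]
    g = _grs_numeric(grs_group)
    d = cohort[diet].to_numpy(dtype=float)
    if np.unique(d).size <= 1:
        raise ModelSpecificationError(f"dietary factor {diet!r} is constant")
    y = cohort[outcome].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "const": np.ones(len(y)),
            "grs": g,
            diet: d,
            "grs:diet": g * d,
        }
    )
    for name in adj:
        X[name] = _design_column(cohort, name)
    if X["grs"].nunique() <= 1:
        raise ModelSpecificationError(f"{outcome}: GRS group is constant")
    res = _ols(y, X, outcome)
    return ModelFit(
        outcome=outcome,
        transformed=transformed,
        model_kind="interaction",
        terms=_terms_frame(res, list(X.columns)),
        adjustment_set=adj,
        n_used=int(res.nobs),
        extras={"diet": diet, "r_squared": float(res.rsquared)},
    )


def stratified_contrast(
    cohort: pd.DataFrame,
    grs_group: pd.Series | np.ndarray,
    tertiles: pd.Series,
    outcome: str,
    adjustment: Sequence[str] | None = None,
    min_cell_n: int = 2,
) -> pd.DataFrame:
    """Low-vs-high GRS comparison of an outcome within each dietary tertile.

    Returns one row per tertile with group means +/- SD, cell sizes, and the
    adjusted between-group p-value (same adjustment rules as
    :func:`fit_association`).  Cells with fewer than ``min_cell_n`` subjects
    in either group are flagged and their p suppressed.
    """
    g = pd.Series(
        np.where(_grs_numeric(grs_group) > 0, "high", "low"), index=cohort.index
    )
    tert = pd.Series(tertiles)
    rows = []
    for t in sorted(tert.unique()):
        in_t = (tert == t).to_numpy()
        sub = cohort.loc[in_t]
        sub_g = g.loc[in_t]
        row: dict[str, object] = {"tertile": t}
        for grp in ("low", "high"):
            vals = sub.loc[(sub_g == grp).to_numpy(), outcome].to_numpy(dtype=float)
            row[f"{grp}_n"] = len(vals)
            row[f"{grp}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{grp}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        flagged = row["low_n"] < min_cell_n or row["high_n"] < min_cell_n
        row["flagged"] = flagged
        if flagged:
            row["p_value"] = np.nan
        else:
            try:
                fit = fit_association(
                    sub.reset_index(drop=True),
                    sub_g.reset_index(drop=True),
                    outcome,
                    adjustment=adjustment,
                )
                row["p_value"] = float(fit.term("grs")["p"])
            except ModelSpecificationError:
                row["flagged"] = True
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
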