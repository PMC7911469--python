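"""Unweighted genetic risk scores and low/high median-split dichotomization.

The score for a subject is the plain count of risk alleles over a panel's
SNPs (each allele contributes 1; ranges 0-10 for the 5-SNP vitamin D panel,
0-20 for the 10-SNP metabolic panel).  Scores are split at the sample median
into a low and a high genetic-risk group.  Two boundary conventions exist in
practice and both are supported: ``le_low`` sends score <= threshold to the
low group (the vitamin D panel convention, e.g. <=2 low / >2 high) and
``lt_low`` sends score < threshold to low (the metabolic panel convention,
e.g. <4 low / >=4 high).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from grsdiet.snp_panel import GenotypeMatrix, SnpDefinition

BOUNDARY_RULES = ("le_low", "lt_low")

#: default dichotomization convention per panel
DEFAULT_BOUNDARY_RULE = {"vitamin_d": "le_low", "metabolic": "lt_low"}


class DegenerateSplitWarning(UserWarning):
    """All subjects fell into a single genetic-risk group."""


@dataclass(frozen=True)
class GrsResult:
    subject_id: str
    panel: str
    score: int
    group: str  # "low" | "high"
    threshold: int
    boundary_rule: str


def compute_grs(
    genotypes: GenotypeMatrix,
    panel: str,
    weights: Callable[[SnpDefinition], float] | None = None,
    missing_policy: str = "complete_case",
) -> tuple[pd.Series, list[str]]:
    """Sum risk-allele dosages over one panel's SNPs.

    Returns ``(scores, dropped)`` where ``scores`` is a Series indexed by
    subject_id and ``dropped`` lists subject ids excluded for missing panel
    calls.  Under the default ``complete_case`` policy a subject with any
    missing panel call is dropped; under ``mean_impute`` each missing call
    is replaced by that SNP's observed mean dosage (scores become
    fractional) and nobody is dropped.  ``weights`` is a hook for per-SNP
    weighting; the default weight is 1 for every SNP (unweighted
    risk-allele count).
    """
    if missing_policy not in ("complete_case", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    cols = [j for j, s in enumerate(genotypes.snps) if s.panel == panel]
    if not cols:
        raise KeyError(f"no SNPs of panel {panel!r} in the genotype matrix")
    w = np.array(
        [1.0 if weights is None else float(weights(genotypes.snps[j])) for j in cols]
    )
    sub = genotypes.dosage[:, cols].astype(float)
    sub_missing = genotypes.missing_mask[:, cols]
    ids = np.asarray(genotypes.subject_ids)
    if missing_policy == "mean_impute" and sub_missing.any():
        masked = np.where(sub_missing, np.nan, sub)
        col_means = np.nanmean(masked, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        sub = np.where(sub_missing, col_means, sub)
        scores = pd.Series(sub @ w, index=ids, name=f"grs_{panel}")
        return scores, []
    complete = ~sub_missing.any(axis=1)
    raw = sub @ w
    scores = pd.Series(
        raw[complete], index=ids[complete], name=f"grs_{panel}"
    )
    if weights is None:
        scores = scores.astype(int)
    dropped = list(ids[~complete])
    return scores, dropped


def median_threshold(scores: Sequence[int]) -> int:
    """Integer split threshold: the sample median, floored when fractional."""
    arr = np.asarray(list(scores))
    if arr.size == 0:
        raise ValueError("cannot take the median of an empty score list")
    return int(math.floor(float(np.median(arr))))


def dichotomize(
    scores: pd.Series | Sequence[int],
    threshold: int,
    boundary_rule: str = "le_low",
) -> pd.DataFrame:
    """Label each score low/high at an integer threshold.

    ``le_low``: score <= threshold -> low, else high.
    ``lt_low``: score <  threshold -> low, else high.
    Emits :class:`DegenerateSplitWarning` when one group is empty.
    """
    if boundary_rule not in BOUNDARY_RULES:
        raise ValueError(f"boundary_rule must be one of {BOUNDARY_RULES}")
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if boundary_rule == "le_low":
        low = s <= threshold
    else:
        low = s < threshold
    out = pd.DataFrame(
        {
            "score": s,
            "group": np.where(low, "low", "high"),
            "threshold": threshold,
            "boundary_rule": boundary_rule,
        },
        index=s.index,
    )
    sizes = out["group"].value_counts()
    if len(sizes) < 2:
        warnings.warn(
            f"degenerate split: all {len(s)} subjects in the "
            f"{sizes.index[0]!r} group",
            DegenerateSplitWarning,
            stacklevel=2,
        )
    return out


def score_panel(
    genotypes: GenotypeMatrix,
    panel: str,
    threshold: int | None = None,
    boundary_rule: str | None = None,
) -> tuple[list[GrsResult], list[str]]:
    """Full scoring for one panel: GRS, median threshold, low/high groups."""
    scores, dropped = compute_grs(genotypes, panel)
    rule = boundary_rule or DEFAULT_BOUNDARY_RULE[panel]
    if threshold is None:
        # the median score itself lands low under le_low and high under lt_low
        threshold = median_threshold(scores)
    labelled = dichotomize(scores, threshold, rule)
    results = [
        GrsResult(
            subject_id=str(idx),
            panel=panel,
            score=int(row["score"]),
            group=str(row["group"]),
            threshold=int(row["threshold"]),
            boundary_rule=str(row["boundary_rule"]),
        )
        for idx, row in labelled.iterrows()
    ]
    return results, dropped
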