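"""End-to-end orchestration: validate -> HWE -> score -> model -> report.

``run_pipeline`` drives the whole analysis over a genotype table, a cohort
table and a SNP panel, writing a reproducible output bundle: an HWE report,
per-panel GRS tables, a descriptive table stratified by vitamin D status
with per-row ANOVA p-values, association fits for both genetic risk scores
against every outcome, GRS x diet interaction fits over the four dietary
factors, tertile-stratified contrasts for nominally significant
interactions, and a JSON run manifest recording every setting a reader
needs to trace a number back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from grsdiet.models import (
    ModelSpecificationError,
    fit_association,
    fit_interaction,
    stratified_contrast,
)
from grsdiet.phenotypes import (
    assign_tertiles,
    descriptive_table,
    log_transform_if_nonnormal,
    validate_cohort,
)
from grsdiet.scoring import DEFAULT_BOUNDARY_RULE, score_panel
from grsdiet.snp_panel import GenotypeMatrix, SnpDefinition, hwe_report, load_genotypes

OUTCOMES = (
    "bmi",
    "wc",
    "bfp",
    "vitd",
    "glucose",
    "hba1c",
    "insulin",
    "tc",
    "hdl",
    "ldl",
    "tg",
)
DIET_FACTORS = ("carb", "protein", "fat", "fiber")

#: variables run through the normality gate before modelling
TRANSFORM_CANDIDATES = OUTCOMES + DIET_FACTORS + ("age", "energy")


class PipelineError(RuntimeError):
    """A pipeline stage failed validation; named after the failing stage."""


@dataclass
class PipelineOptions:
    accept_provisional_panel: bool = False
    alpha: float = 0.05
    interaction_followup_alpha: float = 0.05
    seed: int = 0
    grs_as_score: bool = False  # continuous score instead of median-split group


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _fit_rows(fit, grs_panel: str, term: str, extra: dict) -> dict:
    row = fit.term(term)
    return {
        "panel": grs_panel,
        "outcome": fit.outcome,
        "transformed": fit.transformed,
        "term": term,
        "estimate": float(row["estimate"]),
        "se": float(row["se"]),
        "t": float(row["t"]),
        "p": float(row["p"]),
        "n_used": fit.n_used,
        "adjustment": "+".join(fit.adjustment_set),
        **extra,
    }


def run_pipeline(
    genotypes: GenotypeMatrix | str | Path,
    cohort: pd.DataFrame | str | Path,
    panel: list[SnpDefinition] | None = None,
    out_dir: str | Path | None = None,
    options: PipelineOptions | None = None,
) -> dict:
    """Run the full analysis; return the bundle as a dict of DataFrames.

    When ``out_dir`` is given the bundle is also written as TSV files plus a
    JSON manifest; on any stage failure partial outputs are removed.
    """
    opts = options or PipelineOptions()
    if panel is None:
        from grsdiet.snp_panel import default_panel

        panel = default_panel()

    if any(s.provisional for s in panel) and not opts.accept_provisional_panel:
        raise PipelineError(
            "panel stage: risk-allele orientations are provisional; confirm them "
            "or acknowledge with accept_provisional_panel/--accept-panel"
        )

    # ingest
    if not isinstance(genotypes, GenotypeMatrix):
        genotypes = load_genotypes(genotypes, panel)
    if not isinstance(cohort, pd.DataFrame):
        sep = "\t" if str(cohort).endswith((".tsv", ".txt")) else ","
        cohort = pd.read_csv(cohort, sep=sep)
    try:
        cohort = validate_cohort(cohort)
    except Exception as exc:
        raise PipelineError(f"cohort validation stage: {exc}") from exc

    bundle: dict[str, object] = {}
    bundle["hwe"] = hwe_report(genotypes, alpha=opts.alpha)

    # scoring
    grs_frames = {}
    manifest_scores = {}
    dropped_all: dict[str, list[str]] = {}
    for pnl in ("vitamin_d", "metabolic"):
        results, dropped = score_panel(genotypes, pnl)
        frame = pd.DataFrame([asdict_grs(r) for r in results])
        grs_frames[pnl] = frame
        dropped_all[pnl] = dropped
        manifest_scores[pnl] = {
            "threshold": int(frame["threshold"].iloc[0]),
            "boundary_rule": DEFAULT_BOUNDARY_RULE[pnl],
            "n_low": int((frame["group"] == "low").sum()),
            "n_high": int((frame["group"] == "high").sum()),
            "n_dropped_missing_genotype": len(dropped),
        }
    bundle["grs"] = pd.concat(grs_frames.values(), ignore_index=True)

    # transforms (decided on the full cohort, applied in place for modelling)
    analysed = cohort.copy()
    transform_flags: dict[str, bool] = {}
    for var in TRANSFORM_CANDIDATES:
        if var not in analysed.columns:
            continue
        vals, record = log_transform_if_nonnormal(
            analysed[var].to_numpy(), alpha=opts.alpha, variable=var
        )
        analysed[var] = vals
        transform_flags[var] = record.transformed
    bundle["descriptives"] = descriptive_table(cohort)

    # association + interaction fits
    assoc_rows, inter_rows, strat_tables = [], [], {}
    for pnl, frame in grs_frames.items():
        merged = analysed.merge(
            frame[["subject_id", "score", "group"]], on="subject_id", how="inner"
        )
        predictor = (
            merged["score"].to_numpy(dtype=float)
            if opts.grs_as_score
            else merged["group"]
        )
        for outcome in OUTCOMES:
            try:
                fit = fit_association(
                    merged, predictor, outcome, transformed=transform_flags[outcome]
                )
                assoc_rows.append(_fit_rows(fit, pnl, "grs", {}))
            except ModelSpecificationError as exc:
                raise PipelineError(f"association stage ({pnl}/{outcome}): {exc}")
        for diet in DIET_FACTORS:
            for outcome in OUTCOMES:
                try:
                    fit = fit_interaction(
                        merged,
                        predictor,
                        diet=diet,
                        outcome=outcome,
                        transformed=transform_flags[outcome],
                    )
                except ModelSpecificationError as exc:
                    raise PipelineError(
                        f"interaction stage ({pnl}/{diet}/{outcome}): {exc}"
                    )
                p_int = float(fit.term("grs:diet")["p"])
                inter_rows.append(_fit_rows(fit, pnl, "grs:diet", {"diet": diet}))
                if p_int < opts.interaction_followup_alpha:
                    # localize: stratify by tertiles of raw-scale intake
                    raw = cohort.set_index("subject_id").loc[
                        merged["subject_id"], diet
                    ]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        tert, tert_summary = assign_tertiles(
                            raw.reset_index(drop=True)
                        )
                    strat = stratified_contrast(
                        merged, merged["group"], tert, outcome
                    )
                    strat_tables[f"{pnl}.{diet}.{outcome}"] = {
                        "contrast": strat,
                        "tertiles": tert_summary,
                    }

    assoc = pd.DataFrame(assoc_rows)
    inter = pd.DataFrame(inter_rows)
    for frame in (assoc, inter):
        if len(frame):
            m = len(frame)
            frame["p_bonferroni"] = np.minimum(frame["p"] * m, 1.0)
    bundle["associations"] = assoc
    bundle["interactions"] = inter
    bundle["stratified"] = strat_tables

    manifest = {
        "software_version": _version(),
        "seed": opts.seed,
        "panel_hash": _sha256(
            json.dumps([asdict(s) for s in panel], sort_keys=True)
        ),
        "n_subjects_cohort": int(len(cohort)),
        "scores": manifest_scores,
        "dropped_subjects": dropped_all,
        "transform_flags": transform_flags,
        "grs_predictor": "score" if opts.grs_as_score else "median_split_group",
        "alpha": opts.alpha,
        "outcomes": list(OUTCOMES),
        "diet_factors": list(DIET_FACTORS),
    }
    bundle["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            bundle["hwe"].to_csv(out / "hwe_report.tsv", sep="\t", index=False)
            bundle["grs"].to_csv(out / "grs.tsv", sep="\t", index=False)
            bundle["descriptives"].to_csv(
                out / "descriptives.tsv", sep="\t", index=False
            )
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
            inter.to_csv(out / "interactions.tsv", sep="\t", index=False)
            for key, tables in strat_tables.items():
                tables["contrast"].to_csv(
                    out / f"stratified_{key}.tsv", sep="\t", index=False
                )
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except Exception:
            shutil.rmtree(out, ignore_errors=True)
            raise
    return bundle


def asdict_grs(r) -> dict:
    return {
        "subject_id": r.subject_id,
        "panel": r.panel,
        "score": r.score,
        "group": r.group,
        "threshold": r.threshold,
        "boundary_rule": r.boundary_rule,
    }


def _version() -> str:
    from grsdiet import __version__

    return __version__
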