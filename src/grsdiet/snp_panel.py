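"""SNP panel definitions, risk-allele orientation, and Hardy-Weinberg screening.

A *panel* is a small set of SNPs whose risk alleles are summed into an
unweighted genetic risk score.  Two panels are built in: five vitamin
D-related SNPs (``vitamin_d``) and ten metabolic-disease SNPs
(``metabolic``).  Risk-allele orientation is explicit per SNP rather than
inferred from minor-allele frequency, because minor alleles are
population-dependent (e.g. the DHCR7 rs12785878 minor allele is T in East
and South Asian populations but G in Europeans).
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

VALID_ALLELES = frozenset("ACGT")
PANELS = ("vitamin_d", "metabolic")

#: tokens in a genotype file cell treated as a missing call
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NAN", "./.", ".", "--"})


class PanelConfigError(ValueError):
    """Raised when a panel configuration fails validation."""


class AlleleMismatchError(ValueError):
    """Raised when a genotype call contains an allele not defined for its SNP."""


@dataclass(frozen=True)
class SnpDefinition:
    """One panel entry: a SNP, its risk/other alleles and panel membership.

    ``provisional`` marks entries whose risk-allele orientation is a
    placeholder awaiting confirmation against the source genotyping records
    or GWAS literature; the pipeline refuses to run on a provisional panel
    unless explicitly acknowledged.
    """

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    panel: str
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES:
            raise PanelConfigError(
                f"{self.rsid}: invalid risk allele {self.risk_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise PanelConfigError(
                f"{self.rsid}: invalid other allele {self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise PanelConfigError(
                f"{self.rsid}: risk and other allele are both {self.risk_allele!r}"
            )
        if self.panel not in PANELS:
            raise PanelConfigError(
                f"{self.rsid}: unknown panel {self.panel!r}; expected one of {PANELS}"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.other_allele))


_ALLOWED_KEYS = {"rsid", "gene", "risk_allele", "other_allele", "panel", "provisional"}


def load_panel(config_text: str) -> list[SnpDefinition]:
    """Parse a YAML/JSON panel configuration into validated definitions.

    The document is a list of mappings with keys ``rsid``, ``gene``,
    ``risk_allele``, ``other_allele``, ``panel`` and optional
    ``provisional``.  Unknown keys and duplicate rsIDs are rejected.
    """
    raw = yaml.safe_load(config_text)
    if not isinstance(raw, list) or not raw:
        raise PanelConfigError("panel config must be a non-empty list of SNP entries")
    defs: list[SnpDefinition] = []
    seen: set[str] = set()
    for entry in raw:
        if not isinstance(entry, dict):
            raise PanelConfigError(f"panel entry is not a mapping: {entry!r}")
        unknown = set(entry) - _ALLOWED_KEYS
        if unknown:
            raise PanelConfigError(
                f"unknown fields {sorted(unknown)} in entry {entry.get('rsid', '?')}"
            )
        missing = {"rsid", "gene", "risk_allele", "other_allele", "panel"} - set(entry)
        if missing:
            raise PanelConfigError(
                f"missing fields {sorted(missing)} in entry {entry.get('rsid', '?')}"
            )
        snp = SnpDefinition(
            rsid=str(entry["rsid"]),
            gene=str(entry["gene"]),
            risk_allele=str(entry["risk_allele"]).upper(),
            other_allele=str(entry["other_allele"]).upper(),
            panel=str(entry["panel"]),
            provisional=bool(entry.get("provisional", False)),
        )
        if snp.rsid in seen:
            raise PanelConfigError(f"duplicate rsID {snp.rsid}")
        seen.add(snp.rsid)
        defs.append(snp)
    return defs


def default_panel() -> list[SnpDefinition]:
    """The shipped 15-SNP panel (5 vitamin_d + 10 metabolic).

    Risk-allele orientations are shipped as provisional placeholders drawn
    from the cited GWAS literature and must be confirmed by the user before a
    production run (see the ``provisional`` flag).
    """
    return list(_default_panel_cached())


@functools.lru_cache(maxsize=1)
def _default_panel_cached() -> tuple[SnpDefinition, ...]:
    text = (
        importlib.resources.files("grsdiet.data")
        .joinpath("default_panel.yaml")
        .read_text()
    )
    return tuple(load_panel(text))


def orient_call(
    call: object,
    snp: SnpDefinition,
    coded_allele: str | None = None,
) -> int | None:
    """Convert a raw genotype call to a risk-allele dosage in {0, 1, 2}.

    ``call`` is either an allele-pair string ("AG", "A/G") or an integer
    dosage 0/1/2 of ``coded_allele``.  Dosages coded on the non-risk allele
    are flipped (d -> 2-d).  Missing calls return ``None``.
    """
    if call is None:
        return None
    if isinstance(call, float) and np.isnan(call):
        return None

    if isinstance(call, str):
        token = call.strip().upper().replace("/", "").replace("|", "")
        if call.strip().upper() in MISSING_TOKENS or token in MISSING_TOKENS:
            return None
        if token.isdigit():
            return _orient_dosage(int(token), snp, coded_allele)
        if len(token) != 2:
            raise AlleleMismatchError(
                f"{snp.rsid}: cannot parse genotype call {call!r}"
            )
        bad = set(token) - snp.alleles
        if bad:
            raise AlleleMismatchError(
                f"{snp.rsid}: allele(s) {sorted(bad)} not in "
                f"{{{snp.risk_allele},{snp.other_allele}}}"
            )
        return sum(1 for a in token if a == snp.risk_allele)

    if isinstance(call, (int, np.integer)):
        return _orient_dosage(int(call), snp, coded_allele)

    raise AlleleMismatchError(f"{snp.rsid}: unsupported genotype call {call!r}")


def _orient_dosage(d: int, snp: SnpDefinition, coded_allele: str | None) -> int:
    if d not in (0, 1, 2):
        raise AlleleMismatchError(f"{snp.rsid}: dosage {d} outside {{0,1,2}}")
    if coded_allele is None:
        raise AlleleMismatchError(
            f"{snp.rsid}: numeric dosage requires a declared coded allele"
        )
    coded = coded_allele.upper()
    if coded == snp.risk_allele:
        return d
    if coded == snp.other_allele:
        return 2 - d
    raise AlleleMismatchError(
        f"{snp.rsid}: coded allele {coded!r} not in "
        f"{{{snp.risk_allele},{snp.other_allele}}}"
    )


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs risk-allele dosages with a missingness mask.

    ``dosage[i, j]`` counts copies of ``snps[j].risk_allele`` carried by
    ``subject_ids[i]``; entries under ``missing_mask`` are undefined.
    """

    subject_ids: list[str]
    snps: list[SnpDefinition]
    dosage: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=int)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.dosage.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosage.shape
        if len(self.subject_ids) != n or len(self.snps) != m:
            raise ValueError("dosage shape does not match subject/SNP lists")
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape does not match dosage")
        observed = self.dosage[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing dosages must lie in {0,1,2}")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    def column(self, rsid: str) -> int:
        for j, snp in enumerate(self.snps):
            if snp.rsid == rsid:
                return j
        raise KeyError(f"SNP {rsid} not in genotype matrix")

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n_hom_risk, n_het, n_hom_other) for one SNP, missing excluded."""
        j = self.column(rsid)
        col = self.dosage[:, j][~self.missing_mask[:, j]]
        return int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())


def load_genotypes(
    frame_or_path,
    snps: Sequence[SnpDefinition],
    sep: str | None = None,
    id_column: str = "subject_id",
) -> GenotypeMatrix:
    """Read a wide genotype table (one column per rsID) into a GenotypeMatrix.

    Accepts a path to a CSV/TSV file (header row mandatory) or a DataFrame.
    Cells are two-character allele strings or single-digit dosages (digits
    are taken to count the SNP's risk allele); missing is encoded as an
    empty string, "NA" or "./.".
    """
    if isinstance(frame_or_path, pd.DataFrame):
        df = frame_or_path
    else:
        if sep is None:
            sep = "\t" if str(frame_or_path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(frame_or_path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise PanelConfigError(f"genotype table lacks the {id_column!r} column")
    absent = [s.rsid for s in snps if s.rsid not in df.columns]
    if absent:
        raise PanelConfigError(f"genotype table lacks SNP column(s): {absent}")

    n, m = len(df), len(snps)
    dosage = np.zeros((n, m), dtype=int)
    missing = np.zeros((n, m), dtype=bool)
    for j, snp in enumerate(snps):
        for i, raw in enumerate(df[snp.rsid].tolist()):
            d = orient_call(raw, snp, coded_allele=snp.risk_allele)
            if d is None:
                missing[i, j] = True
            else:
                dosage[i, j] = d
    return GenotypeMatrix(
        subject_ids=[str(s) for s in df[id_column]],
        snps=list(snps),
        dosage=dosage,
        missing_mask=missing,
    )


@dataclass(frozen=True)
class HweResult:
    rsid: str
    counts: tuple[int, int, int]
    chi_square: float
    p_value: float
    in_hwe: bool


def hwe_test(
    counts: tuple[int, int, int],
    rsid: str = "",
    alpha: float = 0.05,
) -> HweResult:
    """Pearson goodness-of-fit chi-square test for Hardy-Weinberg equilibrium.

    ``counts`` is (n_hom_risk, n_het, n_hom_other).  The risk-allele
    frequency p is estimated from the counts; expected genotype counts are
    n*p^2, 2npq, n*q^2 and the statistic is referred to a chi-square with one
    degree of freedom (one allele frequency estimated).  No continuity
    correction.  Monomorphic SNPs return chi_square 0, p 1 by convention.
    """
    n_rr, n_het, n_oo = (int(c) for c in counts)
    if min(n_rr, n_het, n_oo) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_rr + n_het + n_oo
    if n == 0:
        raise ValueError("cannot test HWE on zero genotypes")
    p = (2 * n_rr + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HweResult(rsid, (n_rr, n_het, n_oo), 0.0, 1.0, True)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_rr, n_het, n_oo], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(rsid, (n_rr, n_het, n_oo), chi2, pval, pval > alpha)


def hwe_report(
    genotypes: GenotypeMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-SNP HWE screen over a genotype matrix, as a tidy table."""
    rows = []
    for snp in genotypes.snps:
        counts = genotypes.genotype_counts(snp.rsid)
        res = hwe_test(counts, rsid=snp.rsid, alpha=alpha)
        rows.append(
            {
                "rsid": snp.rsid,
                "gene": snp.gene,
                "panel": snp.panel,
                "n": sum(counts),
                "n_hom_risk": counts[0],
                "n_het": counts[1],
                "n_hom_other": counts[2],
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "in_hwe": res.in_hwe,
            }
        )
    return pd.DataFrame(rows)
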