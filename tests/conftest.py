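import numpy as np
import pandas as pd
import pytest

from grsdiet.snp_panel import GenotypeMatrix, SnpDefinition, default_panel
from grsdiet.synthetic_cohort import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def confirmed_panel(panel):
    """The default panel with the provisional flag cleared, for pipeline runs."""
    return [
        SnpDefinition(
            rsid=s.rsid,
            gene=s.gene,
            risk_allele=s.risk_allele,
            other_allele=s.other_allele,
            panel=s.panel,
            provisional=False,
        )
        for s in panel
    ]


@pytest.fixture(scope="session")
def vitd_snps(panel):
    return [s for s in panel if s.panel == "vitamin_d"]


@pytest.fixture(scope="session")
def sim110():
    """One seeded default cohort at the study's sample size."""
    return simulate_cohort(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def sim5000():
    """One large seeded cohort for asymptotic checks."""
    return simulate_cohort(SimulationParams(seed=11, n_subjects=5000))


def random_genotype_matrix(rng: np.random.Generator, snps, n: int, missing_rate=0.0):
    dosage = rng.integers(0, 3, size=(n, len(snps)))
    missing = rng.random((n, len(snps))) < missing_rate
    ids = [f"R{i}" for i in range(n)]
    return GenotypeMatrix(
        subject_ids=ids, snps=list(snps), dosage=dosage, missing_mask=missing
    )
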