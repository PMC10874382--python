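"""Shared fixtures: small synthetic cohorts reused across the test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mucolink import OmicsMatrix, clr_transform, residualize
from mucolink.synth import SynthConfig, generate_cohort, generate_null_cohort

# the full confounder set of the association models
COVARIATES = [
    "inflammation",
    "location",
    "age",
    "sex",
    "bmi",
    "med_aminosalicylates",
    "med_thiopurines",
    "med_steroids",
    "batch",
]


@pytest.fixture(scope="session")
def covariates():
    return list(COVARIATES)


@pytest.fixture(scope="session")
def cohort():
    """Default 150-patient / 2-biopsy cohort with 2 planted modules."""
    return generate_cohort(SynthConfig(seed=0, n_control_patients=15))


@pytest.fixture(scope="session")
def cohort_clr(cohort):
    return clr_transform(cohort.taxa, pseudocount=0.5)


@pytest.fixture(scope="session")
def null_cohort_small():
    """Signal-free cohort sized for quick per-pair scans."""
    return generate_null_cohort(
        SynthConfig(seed=1, n_patients=100, n_genes=25, n_taxa=10, n_control_patients=0)
    )


@pytest.fixture(scope="session")
def residual_pair(cohort, cohort_clr, covariates):
    """Residualized (taxa, genes) sample x feature frames for sparse CCA."""
    genes_res = residualize(cohort.genes, cohort.meta, covariates)
    clr_mx = OmicsMatrix(cohort_clr.values.T, kind="taxon", unit="clr")
    taxa_res = residualize(clr_mx, cohort.meta, covariates)
    return taxa_res.data.T, genes_res.data.T


def make_counts(arr, samples=None, taxa=None) -> OmicsMatrix:
    """Taxa x samples count matrix from a samples x taxa array."""
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr.T, index=taxa, columns=samples), kind="taxon", unit="counts")
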