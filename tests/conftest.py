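"""Shared fixtures: small genotype/cohort builders and an OLS oracle that is
independent of the package's fitting path (explicit normal equations plus
the t distribution)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxescore.containers import GenotypeMatrix, LongitudinalCohort


def ols_oracle(X, y):
    """Normal-equations least squares with t-based two-sided p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(xtx)))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    return beta, se, pvals


@pytest.fixture
def oracle():
    return ols_oracle


def make_genotypes(counts: dict[str, list], mafs: dict[str, float] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-SNP count lists."""
    frame = pd.DataFrame(counts, dtype=float)
    frame.index = pd.Index([f"I{i+1:03d}" for i in range(len(frame))], name="individual")
    mafs = mafs or {}
    meta = pd.DataFrame(
        {
            "gene": "intergenic",
            "maf": [mafs.get(s, 0.25) for s in frame.columns],
            "minor_allele": None,
        },
        index=pd.Index(frame.columns, name="snp_id"),
    )
    return GenotypeMatrix(counts=frame, meta=meta)


def make_cohort(rows: list[dict]) -> LongitudinalCohort:
    """Build a LongitudinalCohort from partial row dicts (rest defaulted)."""
    defaults = {
        "gender": 0.0,
        "age": 50.0,
        "carb_g": 300.0,
        "fat_g": 30.0,
        "kcal": 1800.0,
        "bodyfat_kg": 17.0,
        "bmi": 24.0,
        "exercise": np.nan,
    }
    records = pd.DataFrame([{**defaults, **r} for r in rows])
    return LongitudinalCohort(records=records)


@pytest.fixture
def genotype_builder():
    return make_genotypes


@pytest.fixture
def cohort_builder():
    return make_cohort
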