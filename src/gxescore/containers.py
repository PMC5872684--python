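"""Core data containers for the sensitivity-profiling pipeline.

The pipeline's tabular objects are thin, validated wrappers around pandas
DataFrames:

``GenotypeMatrix``
    individuals × SNPs additive minor-allele counts (0/1/2, NaN = missing)
    plus per-SNP metadata (gene label, minor allele frequency).
``LongitudinalCohort``
    long-format per-individual per-wave diet, body-composition and exercise
    records with fixed covariates (gender, age).
``CategorySelection``
    the SNPs surviving the gene-environment screen for one effectiveness
    category, with coefficient, p-value and (once assigned) risk-allele sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four effectiveness categories: sensitivity of body-fat change to
#: carbohydrate-intake change, fat-intake change, total-calorie-intake change
#: and exercise onset.
CATEGORIES = ("CE", "FE", "TE", "EE")

#: Sensitivity classes, ordered from least to most sensitive.
CLASSES = ("VL", "L", "H", "VH")

#: Columns of a long-format cohort table.
COHORT_COLUMNS = (
    "individual",
    "wave",
    "gender",
    "age",
    "carb_g",
    "fat_g",
    "kcal",
    "bodyfat_kg",
    "bmi",
    "exercise",
)


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one SNP in the candidate panel.

    Parameters
    ----------
    snp_id : str
        Unique SNP identifier (e.g. an rs number).
    maf : float
        Minor allele frequency, in (0, 0.5].
    gene : str
        Gene label, or ``"intergenic"``.
    minor_allele : str or None
        Optional minor-allele base, needed only for VCF ingestion.
    """

    snp_id: str
    maf: float
    gene: str = "intergenic"
    minor_allele: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(
                f"SNP {self.snp_id}: MAF must lie in (0, 0.5], got {self.maf}"
            )


@dataclass
class GenotypeMatrix:
    """Additive minor-allele counts for a cohort over a SNP panel.

    Attributes
    ----------
    counts : pandas.DataFrame
        Float matrix, index = individual ids, columns = SNP ids; values in
        {0, 1, 2} or NaN for missing calls.
    meta : pandas.DataFrame
        Indexed by snp_id with columns ``gene`` and ``maf`` (and optionally
        ``minor_allele``); row order matches ``counts`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate individual ids: {list(dupes)[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate SNP ids in genotype matrix")
        if list(self.meta.index) != list(self.counts.columns):
            raise ValidationError("SNP metadata does not match genotype columns")
        values = self.counts.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok]
            raise ValidationError(
                f"genotype counts must be 0/1/2 or missing; found {bad[:5]}"
            )
        mafs = self.meta["maf"].to_numpy(dtype=float)
        if ((mafs <= 0) | (mafs > 0.5)).any():
            raise ValidationError("panel MAFs must lie in (0, 0.5]")

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_missing(self) -> int:
        return int(self.counts.isna().to_numpy().sum())

    def column(self, snp_id: str) -> pd.Series:
        if snp_id not in self.counts.columns:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.counts[snp_id]

    def snp_meta(self, snp_id: str) -> SnpMeta:
        row = self.meta.loc[snp_id]
        return SnpMeta(
            snp_id=snp_id,
            maf=float(row["maf"]),
            gene=str(row.get("gene", "intergenic")),
            minor_allele=row.get("minor_allele", None) or None,
        )


@dataclass
class LongitudinalCohort:
    """Long-format survey records: one row per individual per wave.

    Exercise status uses the survey coding 1 = "no", 2 = "yes"; gender is
    coded 0 = male, 1 = female. Waves need not be contiguous per individual.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"cohort table missing columns: {missing_cols}")
        if df.duplicated(subset=["individual", "wave"]).any():
            raise ValidationError("duplicate (individual, wave) records")
        ex = df["exercise"].to_numpy(dtype=float)
        if not (np.isnan(ex) | np.isin(ex, (1.0, 2.0))).all():
            raise ValidationError("exercise status must be coded 1 (no), 2 (yes) or missing")
        for col in ("carb_g", "fat_g", "kcal", "bodyfat_kg"):
            vals = df[col].to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError(f"negative values in {col}")

    @property
    def individuals(self) -> list:
        return list(pd.unique(self.records["individual"]))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def covariates(self) -> pd.DataFrame:
        """Per-individual gender and age (first observed record)."""
        return (
            self.records.sort_values("wave")
            .groupby("individual", sort=False)[["gender", "age"]]
            .first()
        )


@dataclass
class CategorySelection:
    """SNPs selected for one effectiveness category.

    ``table`` has one row per SNP with columns ``snp_id``, ``coef``, ``p``
    and ``sign`` (NaN until :func:`gxescore.grs.assign_signs` runs).
    """

    category: str
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "coef", "p", "sign"])
    )

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        for col in ("snp_id", "coef", "p"):
            if col not in self.table.columns:
                raise ValidationError(f"selection table missing column {col!r}")
        if "sign" not in self.table.columns:
            self.table = self.table.assign(sign=np.nan)
        if self.table["snp_id"].duplicated().any():
            raise ValidationError("duplicate SNP in category selection")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_signed(self) -> bool:
        return len(self.table) > 0 and self.table["sign"].notna().all()
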