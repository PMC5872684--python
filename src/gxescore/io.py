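"""Plain-text input/output for the pipeline's tables.

All files are tab-delimited UTF-8 with a single header row; missing values
are written as ``NA``. Genotypes travel as a wide table (rows = individuals,
columns = SNP ids); cohort phenotypes as a long table (one row per
individual per wave). An optional VCF reader produces the same
:class:`~gxescore.containers.GenotypeMatrix`, counting copies of the panel's
stated minor allele rather than the VCF ALT allele.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    COHORT_COLUMNS,
    GenotypeMatrix,
    LongitudinalCohort,
    SnpMeta,
    ValidationError,
)

logger = logging.getLogger(__name__)

_NA = "NA"
_SEP = "\t"


def read_panel(path: str | Path) -> list[SnpMeta]:
    """Read a SNP panel TSV (snp_id, gene, maf[, minor_allele])."""
    df = pd.read_csv(path, sep=_SEP, na_values=[_NA], dtype={"snp_id": str}, float_precision="round_trip")
    required = {"snp_id", "gene", "maf"}
    if not required.issubset(df.columns):
        raise ValidationError(f"panel file must have columns {sorted(required)}")
    if df["snp_id"].duplicated().any():
        raise ValidationError("duplicate snp_id in panel")
    has_allele = "minor_allele" in df.columns
    return [
        SnpMeta(
            snp_id=row.snp_id,
            maf=float(row.maf),
            gene=str(row.gene),
            minor_allele=(str(row.minor_allele) if has_allele and pd.notna(row.minor_allele) else None),
        )
        for row in df.itertuples()
    ]


def _meta_frame(panel: list[SnpMeta]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": [m.gene for m in panel],
            "maf": [m.maf for m in panel],
            "minor_allele": [m.minor_allele for m in panel],
        },
        index=pd.Index([m.snp_id for m in panel], name="snp_id"),
    )
    return df


def read_genotypes(
    path: str | Path, panel: list[SnpMeta] | None = None
) -> GenotypeMatrix:
    """Read a wide genotype TSV into a validated :class:`GenotypeMatrix`.

    The first column holds individual ids; remaining columns are SNP ids.
    Cells outside {0, 1, 2} (including non-numeric junk) become missing and
    are counted in a logged warning rather than failing the load. Duplicate
    individual ids are a hard error.

    If ``panel`` is omitted, metadata is synthesised with the empirical MAF
    of each column (clipped into (0, 0.5]) and gene label "intergenic".
    """
    df = pd.read_csv(path, sep=_SEP, na_values=[_NA], index_col=0, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValidationError(f"empty genotype file: {path}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"duplicate individual ids in {path}: {list(dupes)[:5]}")

    values = df.apply(pd.to_numeric, errors="coerce")
    invalid = values.notna() & ~values.isin((0.0, 1.0, 2.0))
    n_coerced = int((df.notna() & values.isna()).to_numpy().sum())
    n_invalid = int(invalid.to_numpy().sum())
    if n_coerced + n_invalid:
        logger.warning(
            "%s: %d cell(s) outside {0,1,2} set to missing", path, n_coerced + n_invalid
        )
    values = values.mask(invalid)
    values.index.name = "individual"

    if panel is not None:
        meta = _meta_frame(panel)
        missing = [s for s in values.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"genotype columns not in panel: {missing[:5]}")
        meta = meta.loc[values.columns]
        meta.index.name = "snp_id"
    else:
        emp_maf = values.mean(axis=0) / 2.0
        emp_maf = np.minimum(emp_maf, 1.0 - emp_maf)  # fold to the minor allele
        meta = pd.DataFrame(
            {
                "gene": "intergenic",
                "maf": emp_maf.clip(lower=1e-6, upper=0.5),
                "minor_allele": None,
            },
        )
        meta.index.name = "snp_id"
    gm = GenotypeMatrix(counts=values.astype(float), meta=meta)
    gm.n_warnings = n_coerced + n_invalid
    return gm


def read_vcf_genotypes(path: str | Path, panel: list[SnpMeta]) -> GenotypeMatrix:
    """Read genotypes from a VCF 4.x file for the SNPs in ``panel``.

    Counts copies of each SNP's *stated minor allele* (``SnpMeta.minor_allele``,
    matched against REF/ALT), which may differ from the ALT allele — the
    additive coding used throughout is minor-allele based. Panel SNPs absent
    from the VCF, or whose minor allele matches neither REF nor ALT, come
    back all-missing with a logged warning.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    by_id = {m.snp_id: m for m in panel}
    for m in panel:
        if m.minor_allele is None:
            raise ValidationError(
                f"panel SNP {m.snp_id} lacks a minor_allele; required for VCF input"
            )
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    counts = pd.DataFrame(
        np.nan,
        index=pd.Index(individuals, name="individual"),
        columns=[m.snp_id for m in panel],
        dtype=float,
    )
    seen = set()
    for variant in vcf:
        meta = by_id.get(variant.ID)
        if meta is None:
            continue
        seen.add(variant.ID)
        alleles = [variant.REF] + list(variant.ALT)
        if meta.minor_allele not in alleles:
            logger.warning(
                "%s: minor allele %s not among VCF alleles %s; left missing",
                variant.ID, meta.minor_allele, alleles,
            )
            continue
        minor_idx = alleles.index(meta.minor_allele)
        # gt_types not used: count minor-allele copies explicitly per sample
        col = np.full(len(individuals), np.nan)
        for i, gt in enumerate(variant.genotypes):
            calls = [a for a in gt[:2] if a >= 0]
            if len(calls) == 2:
                col[i] = sum(1 for a in calls if a == minor_idx)
        counts[variant.ID] = col
    unseen = set(by_id) - seen
    if unseen:
        logger.warning("%d panel SNP(s) absent from VCF", len(unseen))
    return GenotypeMatrix(counts=counts, meta=_meta_frame(panel))


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a wide TSV (counts printed as integers)."""
    out = genotypes.counts.copy()
    out.index.name = "individual"
    out.to_csv(path, sep=_SEP, na_rep=_NA, float_format="%.0f")


def read_cohort(path: str | Path) -> LongitudinalCohort:
    """Read a long-format cohort TSV into a validated cohort.

    Unknown exercise codes and negative body-fat values are hard errors
    (delegated to container validation); waves may be non-contiguous.
    """
    df = pd.read_csv(path, sep=_SEP, na_values=[_NA], dtype={"individual": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns: {missing}")
    for col in ("wave", "gender", "age", "carb_g", "fat_g", "kcal", "bodyfat_kg", "bmi", "exercise"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return LongitudinalCohort(records=df)


def write_cohort(cohort: LongitudinalCohort, path: str | Path) -> None:
    cohort.records.to_csv(path, sep=_SEP, na_rep=_NA, index=False)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with header.

    Floats are printed in shortest round-trip form, so a read-back
    reproduces every value bit-for-bit. Empty tables are an error: every
    pipeline artifact is expected to carry at least one row.
    """
    if records is None or len(records) == 0:
        raise ValidationError(f"refusing to write empty table to {path}")
    records.to_csv(
        path,
        sep=_SEP,
        na_rep=_NA,
        index=bool(records.index.name),
    )


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    df = pd.read_csv(path, sep=_SEP, na_values=[_NA], float_precision="round_trip")
    if index_col is not None:
        df = df.set_index(index_col)
    return df
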