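"""Signed genetic risk scores and quartile sensitivity classes.

Each surviving SNP is assigned a sign from its screening coefficient: +1
for a positive coefficient, −1 for a negative one. The sign is *reversed*
for the exercise category (EE), where a positive SNP main effect means the
allele promotes weight gain on exercise onset — i.e. works against the
intervention — so the score should count it negatively.

The GRS is the unweighted signed allele count Σ sign_i × count_i: an
integer when no genotype is missing; a missing call contributes its
expected count 2·maf instead of zero, so carriers of missing genotypes are
not dragged toward the insensitive end.

Classes come from the population GRS quartiles: VL below the 25th
percentile, L in [25th, 50th), H in [50th, 75th), VH at or above the 75th.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CATEGORIES, CategorySelection, GenotypeMatrix, ValidationError

#: percentile estimators: "linear" interpolates between order statistics at
#: position 1 + p(n−1); "nearest-rank" is the inverted-CDF order statistic.
PERCENTILE_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


@dataclass(frozen=True)
class QuartileCutpoints:
    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValidationError("quartile cutpoints must be non-decreasing")


def assign_signs(selection: CategorySelection) -> CategorySelection:
    """Assign each SNP's risk-allele sign from its coefficient.

    CE/FE/TE: sign = +1 if the interaction coefficient is positive else −1.
    EE: reversed (+1 for a negative main effect). A coefficient of exactly
    zero has no defined sign and is an error.
    """
    table = selection.table.copy()
    if len(table) == 0:
        return CategorySelection(category=selection.category, table=table)
    if (table["coef"] == 0).any():
        zero = table.loc[table["coef"] == 0, "snp_id"].tolist()
        raise ValidationError(f"zero coefficient has undefined sign: {zero}")
    sign = np.where(table["coef"] > 0, 1.0, -1.0)
    if selection.category == "EE":
        sign = -sign
    table["sign"] = sign
    return CategorySelection(category=selection.category, table=table)


def compute_grs(genotypes: GenotypeMatrix, selection: CategorySelection) -> pd.Series:
    """Per-individual signed risk-allele sum for one category.

    Missing genotypes contribute sign × 2·maf (the expected count under
    HWE). An empty selection yields all-zero scores.
    """
    scores = pd.Series(0.0, index=genotypes.counts.index, name=f"{selection.category}_grs")
    if len(selection.table) == 0:
        return scores
    if not selection.is_signed:
        raise ValidationError("selection must be signed before scoring (assign_signs)")
    missing = [s for s in selection.snp_ids if s not in genotypes.counts.columns]
    if missing:
        raise ValidationError(f"selection SNPs absent from genotype matrix: {missing}")
    snps = selection.snp_ids
    expected = 2.0 * genotypes.meta.loc[snps, "maf"]
    counts = genotypes.counts[snps].fillna(expected)
    signs = selection.table.set_index("snp_id").loc[snps, "sign"].astype(float)
    return (counts @ signs).rename(f"{selection.category}_grs")


def quartile_cutpoints(grs: pd.Series | np.ndarray, method: str = "linear") -> QuartileCutpoints:
    """25th/50th/75th percentiles of a population GRS distribution."""
    values = np.asarray(grs, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 4:
        raise ValidationError(f"need at least 4 individuals for quartiles, got {len(values)}")
    if method not in PERCENTILE_METHODS:
        raise ValidationError(f"unknown percentile method {method!r}")
    q25, q50, q75 = np.percentile(values, [25, 50, 75], method=PERCENTILE_METHODS[method])
    return QuartileCutpoints(q25=float(q25), q50=float(q50), q75=float(q75))


def classify(grs: float, cuts: QuartileCutpoints) -> str:
    """Map one score to its sensitivity class (boundaries round up)."""
    if grs < cuts.q25:
        return "VL"
    if grs < cuts.q50:
        return "L"
    if grs < cuts.q75:
        return "H"
    return "VH"


def classify_series(grs: pd.Series, cuts: QuartileCutpoints) -> pd.Series:
    codes = np.select(
        [grs < cuts.q25, grs < cuts.q50, grs < cuts.q75],
        ["VL", "L", "H"],
        default="VH",
    )
    return pd.Series(codes, index=grs.index, name=grs.name.replace("_grs", "_class") if grs.name else "class")


def build_profiles(
    genotypes: GenotypeMatrix,
    selections: dict[str, CategorySelection],
    method: str = "linear",
    cutpoints: dict[str, QuartileCutpoints] | None = None,
) -> tuple[pd.DataFrame, dict[str, QuartileCutpoints]]:
    """Sensitivity profile per individual: four scores and four classes.

    Cutpoints are computed on the scored population itself unless a stored
    ``cutpoints`` mapping is supplied (to classify new individuals against
    an existing reference distribution). Categories with an empty selection
    produce all-zero scores and degenerate all-VH classes, which the caller
    should treat as uninformative.
    """
    profile = pd.DataFrame(index=genotypes.counts.index)
    out_cuts: dict[str, QuartileCutpoints] = {}
    for category in CATEGORIES:
        selection = selections.get(category, CategorySelection(category=category))
        scores = compute_grs(genotypes, selection)
        cuts = (
            cutpoints[category]
            if cutpoints is not None
            else quartile_cutpoints(scores, method=method)
        )
        out_cuts[category] = cuts
        profile[f"{category}_grs"] = scores
        profile[f"{category}_class"] = classify_series(scores, cuts)
    profile.index.name = "individual"
    return profile, out_cuts
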