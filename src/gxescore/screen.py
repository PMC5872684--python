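"""Per-SNP gene-environment regression screen.

Three Gaussian linear models are fitted per SNP by ordinary least squares
(the identity-link Gaussian GLM used for a continuous response), with
two-sided t-tests on each coefficient:

* diet model —      Δbodyfat ~ gender + age + ΔTC + SNP + ΔC + ΔF
                    + ΔC×SNP (target β_c, category CE)
                    + ΔF×SNP (target β_f, category FE)
* calorie model —   Δbodyfat ~ gender + age + ΔTC + SNP + ΔTC×SNP
                    (target β_TC, category TE)
* exercise model —  Δbodyfat* ~ gender + age + SNP
                    (target β_E, category EE)

A SNP enters a category when its target-term p-value is strictly below the
selection α (0.05 by default, uncorrected; an optional Benjamini-Hochberg
flag is available). Fits are complete-case per model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CategorySelection, GenotypeMatrix, ValidationError

#: target regression term per category
TARGET_TERMS = {
    "CE": "d_carb:snp",
    "FE": "d_fat:snp",
    "TE": "d_kcal:snp",
    "EE": "snp",
}

#: model id providing each category's target term
CATEGORY_MODEL = {"CE": 1, "FE": 1, "TE": 2, "EE": 3}


class RankDeficientError(ValidationError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass
class OlsFit:
    """Least-squares fit summary: per-term estimate, SE and two-sided t p."""

    params: pd.DataFrame  # index = term, columns = coef, se, p
    n_used: int
    df_resid: int
    rss: float

    def term(self, name: str) -> tuple[float, float, float]:
        row = self.params.loc[name]
        return float(row["coef"]), float(row["se"]), float(row["p"])


@dataclass
class FitResult:
    """One SNP × one model, with the category target terms flagged."""

    snp_id: str
    model: int
    fit: OlsFit
    targets: dict[str, str]  # category -> term name

    def target(self, category: str) -> tuple[float, float, float]:
        return self.fit.term(self.targets[category])


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in a linear dependency (by rank drop on removal)."""
    full_rank = np.linalg.matrix_rank(X)
    involved = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            # removing the column loses nothing: it lies in the others' span
            involved.append(name)
    return involved or names


def fit_ols(design: pd.DataFrame, response: pd.Series | np.ndarray) -> OlsFit:
    """OLS with t-based inference on a complete-case design.

    The design must include its intercept column. SEs use the unbiased
    residual variance; p-values are two-sided t with n − p degrees of
    freedom. Rank-deficient designs raise :class:`RankDeficientError`
    naming the collinear terms; n ≤ p raises ``ValidationError``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("design/response shape mismatch")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("fit_ols requires complete cases (no NaN)")
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"insufficient observations: n={n} <= terms={p}")
    names = list(design.columns)
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_terms(X, names)
        raise RankDeficientError(f"rank-deficient design; collinear terms: {bad}")

    res = sm.OLS(y, X).fit()
    params = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues},
        index=pd.Index(names, name="term"),
    )
    return OlsFit(params=params, n_used=n, df_resid=int(res.df_resid), rss=float(res.ssr))


def _complete_design(frame: pd.DataFrame, response_col: str) -> tuple[pd.DataFrame, pd.Series]:
    complete = frame.dropna()
    y = complete[response_col]
    X = complete.drop(columns=[response_col])
    return X, y


def fit_model_diet(
    deltas: pd.DataFrame, genotypes: GenotypeMatrix, snp_id: str
) -> FitResult:
    """Diet model: interaction of a SNP with carbohydrate- and fat-intake change."""
    g = genotypes.column(snp_id)
    frame = pd.DataFrame(
        {
            "d_bodyfat": deltas["d_bodyfat"],
            "const": 1.0,
            "gender": deltas["gender"],
            "age": deltas["age"],
            "d_kcal": deltas["d_kcal"],
            "snp": g.reindex(deltas.index),
            "d_carb": deltas["d_carb"],
            "d_fat": deltas["d_fat"],
        }
    )
    frame["d_carb:snp"] = frame["d_carb"] * frame["snp"]
    frame["d_fat:snp"] = frame["d_fat"] * frame["snp"]
    X, y = _complete_design(frame, "d_bodyfat")
    fit = fit_ols(X, y)
    return FitResult(snp_id=snp_id, model=1, fit=fit,
                     targets={"CE": "d_carb:snp", "FE": "d_fat:snp"})


def fit_model_calorie(
    deltas: pd.DataFrame, genotypes: GenotypeMatrix, snp_id: str
) -> FitResult:
    """Calorie model: interaction of a SNP with total-calorie-intake change."""
    g = genotypes.column(snp_id)
    frame = pd.DataFrame(
        {
            "d_bodyfat": deltas["d_bodyfat"],
            "const": 1.0,
            "gender": deltas["gender"],
            "age": deltas["age"],
            "d_kcal": deltas["d_kcal"],
            "snp": g.reindex(deltas.index),
        }
    )
    frame["d_kcal:snp"] = frame["d_kcal"] * frame["snp"]
    X, y = _complete_design(frame, "d_bodyfat")
    fit = fit_ols(X, y)
    return FitResult(snp_id=snp_id, model=2, fit=fit, targets={"TE": "d_kcal:snp"})


def fit_model_exercise(
    deltas: pd.DataFrame, genotypes: GenotypeMatrix, snp_id: str
) -> FitResult:
    """Exercise model: SNP main effect on the oriented body-fat delta Δbodyfat*."""
    if "d_bodyfat_star" not in deltas.columns:
        raise ValidationError("exercise model requires the d_bodyfat_star column")
    g = genotypes.column(snp_id)
    frame = pd.DataFrame(
        {
            "d_bodyfat_star": deltas["d_bodyfat_star"],
            "const": 1.0,
            "gender": deltas["gender"],
            "age": deltas["age"],
            "snp": g.reindex(deltas.index),
        }
    )
    X, y = _complete_design(frame, "d_bodyfat_star")
    fit = fit_ols(X, y)
    return FitResult(snp_id=snp_id, model=3, fit=fit, targets={"EE": "snp"})


def screen_panel(
    diet_deltas: pd.DataFrame | None,
    exercise_deltas: pd.DataFrame | None,
    genotypes: GenotypeMatrix,
    min_carriers: int = 5,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every applicable model for every SNP in the panel.

    SNPs whose minor-genotype carrier count (individuals with ≥ 1 minor
    allele among non-missing calls) is below ``min_carriers`` — or whose
    genotype column is constant — are skipped rather than fitted unstably;
    the second return value logs (snp_id, reason) for each skip.
    """
    fits: list[FitResult] = []
    skipped: list[dict] = []
    for snp_id in genotypes.snp_ids:
        col = genotypes.column(snp_id).dropna()
        carriers = int((col > 0).sum())
        if carriers < min_carriers:
            skipped.append({"snp_id": snp_id, "reason": f"carriers={carriers}<{min_carriers}"})
            continue
        if col.nunique() < 2:
            skipped.append({"snp_id": snp_id, "reason": "monomorphic"})
            continue
        try:
            if diet_deltas is not None:
                fits.append(fit_model_diet(diet_deltas, genotypes, snp_id))
                fits.append(fit_model_calorie(diet_deltas, genotypes, snp_id))
            if exercise_deltas is not None and len(exercise_deltas):
                fits.append(fit_model_exercise(exercise_deltas, genotypes, snp_id))
        except RankDeficientError as exc:
            skipped.append({"snp_id": snp_id, "reason": str(exc)})
    skip_log = pd.DataFrame(skipped, columns=["snp_id", "reason"])
    return fits, skip_log


def select_snps(
    fits: list[FitResult], alpha: float = 0.05, bh_correct: bool = False
) -> dict[str, CategorySelection]:
    """Select SNPs per category by target-term p-value strictly below α.

    A SNP may appear in several categories (its diet- and calorie-model
    target terms are tested independently). ``bh_correct=True`` applies a
    Benjamini-Hochberg adjustment within each category first; the study
    procedure uses raw p-values, so it is off by default.
    """
    selections: dict[str, CategorySelection] = {}
    for category, model_id in CATEGORY_MODEL.items():
        rows = []
        for fr in fits:
            if fr.model != model_id or category not in fr.targets:
                continue
            coef, _se, p = fr.target(category)
            rows.append({"snp_id": fr.snp_id, "coef": coef, "p": p})
        table = pd.DataFrame(rows, columns=["snp_id", "coef", "p"])
        if len(table) and bh_correct:
            from statsmodels.stats.multitest import multipletests

            _, p_adj, _, _ = multipletests(table["p"], method="fdr_bh")
            keep = p_adj < alpha
        else:
            keep = table["p"] < alpha
        selected = table[keep].sort_values("p", kind="stable").reset_index(drop=True)
        selections[category] = CategorySelection(category=category, table=selected)
    return selections
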