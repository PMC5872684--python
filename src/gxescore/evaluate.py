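"""Evaluation of the sensitivity classes on responder subgroups.

For each diet category the *responder subset* holds the individuals whose
intake change lies below the first quartile of that change's distribution —
the largest reducers of carbohydrate, fat or total calories; for exercise it
holds the individuals who experienced at least one exercise onset. Within a
responder subset the mean body-fat change is summarised per sensitivity
class: an informative score should show increasing fat loss from VL to VH.
A simple ordinal trend (OLS of the individual outcome on the class code
VL=0 … VH=3) quantifies that monotone pattern; descriptive statistics with
a Shapiro-Wilk normality test summarise each GRS distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CATEGORIES, CLASSES, ValidationError

logger = logging.getLogger(__name__)

#: delta column examined per category
OUTCOME_COLUMN = {"CE": "d_bodyfat", "FE": "d_bodyfat", "TE": "d_bodyfat", "EE": "d_bodyfat_star"}
CHANGE_COLUMN = {"CE": "d_carb", "FE": "d_fat", "TE": "d_kcal"}

_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}


def responder_subset(deltas: pd.DataFrame, category: str) -> pd.Index:
    """Individuals in the responder subgroup for one category.

    CE/FE/TE: intake change strictly below the 25th percentile (linear
    interpolation) of its own distribution. EE: at least one no→yes
    transition (requires the ``n_onsets`` column from the exercise delta
    derivation).
    """
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    if category == "EE":
        if "n_onsets" not in deltas.columns:
            raise ValidationError("EE responder subset requires the n_onsets column")
        subset = deltas.index[deltas["n_onsets"] >= 1]
    else:
        col = deltas[CHANGE_COLUMN[category]].dropna()
        q1 = np.percentile(col.to_numpy(), 25)
        subset = col.index[col < q1]
    if len(subset) == 0:
        logger.warning("empty responder subset for category %s", category)
    return subset


def group_means(
    subset: pd.Index, profiles: pd.DataFrame, deltas: pd.DataFrame, category: str
) -> pd.DataFrame:
    """n, mean and SD of the body-fat change per class within a subset.

    Classes with no members are reported with n = 0 and missing mean/SD so
    that the four rows always sum to the responder-subset size.
    """
    outcome_col = OUTCOME_COLUMN[category]
    class_col = f"{category}_class"
    members = profiles.loc[profiles.index.intersection(subset)]
    outcome = deltas.loc[members.index, outcome_col]
    rows = []
    for cls in CLASSES:
        vals = outcome[members[class_col] == cls].dropna()
        rows.append(
            {
                "category": category,
                "class": cls,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def trend_statistic(
    subset: pd.Index, profiles: pd.DataFrame, deltas: pd.DataFrame, category: str
) -> tuple[float, float]:
    """Ordinal-trend slope of the individual outcome on class code VL=0…VH=3.

    Returns (slope, two-sided p). Requires members in at least two classes.
    """
    class_col = f"{category}_class"
    outcome_col = OUTCOME_COLUMN[category]
    members = profiles.loc[profiles.index.intersection(subset)]
    frame = pd.DataFrame(
        {
            "code": members[class_col].map(_CLASS_CODE).astype(float),
            "y": deltas.loc[members.index, outcome_col],
        }
    ).dropna()
    if frame["code"].nunique() < 2:
        raise ValidationError(
            f"trend for {category} needs members in >= 2 classes, got {frame['code'].nunique()}"
        )
    res = stats.linregress(frame["code"], frame["y"])
    return float(res.slope), float(res.pvalue)


def grs_descriptives(
    grs_by_category: dict[str, pd.Series],
    max_shapiro_n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean, SD, median, min, max and Shapiro-Wilk p per GRS distribution.

    The Shapiro-Wilk test runs on a seeded subsample of ``max_shapiro_n``
    when the population is larger (the test loses meaning — and scipy
    warns — at very large n); constant vectors report a missing p.
    Fewer than 3 observations is an error for the test; descriptives are
    still returned for n >= 1.
    """
    rows = []
    for category, scores in grs_by_category.items():
        values = np.asarray(scores.dropna(), dtype=float)
        if len(values) == 0:
            raise ValidationError(f"no scores for category {category}")
        row = {
            "category": category,
            "n": int(len(values)),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else np.nan,
            "median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max()),
        }
        if len(values) < 3:
            raise ValidationError(f"Shapiro-Wilk needs n >= 3 for {category}")
        if np.ptp(values) == 0.0:
            row["shapiro_p"] = np.nan
        else:
            sample = values
            if len(values) > max_shapiro_n:
                rng = np.random.default_rng(seed)
                sample = rng.choice(values, size=max_shapiro_n, replace=False)
                logger.info(
                    "%s: Shapiro-Wilk on a subsample of %d of %d scores",
                    category, max_shapiro_n, len(values),
                )
            row["shapiro_p"] = float(stats.shapiro(sample).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_all(
    profiles: pd.DataFrame,
    diet_deltas: pd.DataFrame,
    exercise_deltas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Responder-subgroup class summaries for every category with data."""
    summaries = []
    for category in CATEGORIES:
        deltas = exercise_deltas if category == "EE" else diet_deltas
        if deltas is None or len(deltas) == 0:
            continue
        subset = responder_subset(deltas, category)
        if len(subset) == 0:
            continue
        summaries.append(group_means(subset, profiles, deltas, category))
    if not summaries:
        return pd.DataFrame(columns=["category", "class", "n", "mean", "sd"])
    return pd.concat(summaries, ignore_index=True)
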