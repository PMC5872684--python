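"""Per-individual analysis variables derived from the longitudinal records.

Two derivations feed the regression screen:

* dietary deltas between a baseline and a follow-up wave
  (Δbodyfat, ΔC, ΔF, ΔTC = follow-up − baseline), and
* the orientation-normalised exercise body-fat delta Δbodyfat*: over
  consecutive observed waves where exercise status changed, the body fat at
  the exercising ("yes") wave minus that at the non-exercising ("no") wave,
  averaged per individual. The statistic is direction-free: reversing an
  individual's timeline leaves it unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import LongitudinalCohort, ValidationError

DIET_DELTA_COLUMNS = ("d_bodyfat", "d_carb", "d_fat", "d_kcal")


def compute_diet_deltas(
    cohort: LongitudinalCohort, baseline_wave: int = 0, followup_wave: int = 3
) -> pd.DataFrame:
    """Change scores between two survey waves.

    Returns a DataFrame indexed by individual with columns ``gender``,
    ``age``, ``d_bodyfat`` (kg), ``d_carb`` (g/day), ``d_fat`` (g/day) and
    ``d_kcal`` (kcal/day). Individuals missing either wave, or missing any
    of the four phenotype fields at either wave, are excluded; the exclusion
    count is available as ``result.attrs["n_excluded"]``.
    """
    if baseline_wave == followup_wave:
        raise ValidationError("baseline and follow-up waves must differ")
    df = cohort.records
    fields = ["carb_g", "fat_g", "kcal", "bodyfat_kg"]
    base = df[df["wave"] == baseline_wave].set_index("individual")
    fup = df[df["wave"] == followup_wave].set_index("individual")

    common = base.index.intersection(fup.index)
    b = base.loc[common, fields]
    f = fup.loc[common, fields]
    complete = b.notna().all(axis=1) & f.notna().all(axis=1)
    kept = common[complete]

    deltas = pd.DataFrame(
        {
            "gender": base.loc[kept, "gender"],
            "age": base.loc[kept, "age"],
            "d_bodyfat": f.loc[kept, "bodyfat_kg"] - b.loc[kept, "bodyfat_kg"],
            "d_carb": f.loc[kept, "carb_g"] - b.loc[kept, "carb_g"],
            "d_fat": f.loc[kept, "fat_g"] - b.loc[kept, "fat_g"],
            "d_kcal": f.loc[kept, "kcal"] - b.loc[kept, "kcal"],
        }
    )
    deltas.index.name = "individual"
    n_total = df["individual"].nunique()
    deltas.attrs["n_excluded"] = int(n_total - len(deltas))
    return deltas


def compute_exercise_delta(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Averaged oriented body-fat difference across exercise-status changes.

    For each individual, consecutive *observed* waves with non-missing
    status are scanned; every pair where the status changes contributes the
    oriented difference (body fat at the "yes" wave) − (body fat at the "no"
    wave). Pairs with a missing body-fat value are skipped. Individuals with
    no usable status change are excluded.

    Returns a DataFrame indexed by individual with columns ``gender``,
    ``age``, ``d_bodyfat_star`` (kg), ``n_transitions`` and ``n_onsets``
    (the number of no→yes changes in time order, used to define the
    exercise-responder subset).
    """
    df = cohort.records.sort_values(["individual", "wave"])
    out = []
    for ind, grp in df.groupby("individual", sort=False):
        obs = grp[grp["exercise"].notna()]
        status = obs["exercise"].to_numpy()
        fat = obs["bodyfat_kg"].to_numpy()
        diffs: list[float] = []
        n_onsets = 0
        for t in range(1, len(obs)):
            s_prev, s_curr = status[t - 1], status[t]
            if s_prev == s_curr:
                continue
            if s_prev == 1 and s_curr == 2:
                n_onsets += 1
            if np.isnan(fat[t - 1]) or np.isnan(fat[t]):
                continue
            yes_fat = fat[t] if s_curr == 2 else fat[t - 1]
            no_fat = fat[t - 1] if s_curr == 2 else fat[t]
            diffs.append(yes_fat - no_fat)
        if diffs:
            out.append(
                {
                    "individual": ind,
                    "gender": grp["gender"].iloc[0],
                    "age": grp["age"].iloc[0],
                    "d_bodyfat_star": float(np.mean(diffs)),
                    "n_transitions": len(diffs),
                    "n_onsets": n_onsets,
                }
            )
    if not out:
        result = pd.DataFrame(
            columns=["gender", "age", "d_bodyfat_star", "n_transitions", "n_onsets"]
        )
        result.index.name = "individual"
        return result
    result = pd.DataFrame(out).set_index("individual")
    return result
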