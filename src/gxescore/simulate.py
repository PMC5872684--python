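"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a panel
of Hardy-Weinberg genotypes (optionally in LD blocks), a two-wave dietary
study whose intake and body-fat *changes* match the marginal moments of a
large Korean population cohort, a five-wave exercise series with a two-state
status chain, and configurable planted SNP main/interaction effects so that
every stage of the screen → prune → score → classify → evaluate pipeline can
be tested with known ground truth.

Default marginals (means ± SDs of the dietary deltas, the body-fat delta,
age, baseline intakes, the exercise transition rate) follow the published
cohort characteristics; see ``docs/methods.md`` for the provenance of each
number and for the total-calorie construction ΔTC = 4·ΔC + 9·ΔF + noise
(Atwater energy factors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CATEGORIES,
    GenotypeMatrix,
    LongitudinalCohort,
    ValidationError,
)

# Wave labels: FFQ diet data at baseline (0) and third follow-up (3);
# exercise status surveyed at follow-ups 3-7.
DIET_WAVES = (0, 3)
EXERCISE_WAVES = (3, 4, 5, 6, 7)

# Independent substreams of the master seed.
_STREAM_GENO, _STREAM_DIET, _STREAM_EXER, _STREAM_COVAR = range(4)


@dataclass(frozen=True)
class EffectSpec:
    """A planted per-SNP effect.

    ``beta`` is the interaction coefficient for CE/FE (kg body fat per
    g·allele), TE (kg per kcal·allele), or the per-allele main effect for EE
    (kg per allele per exercise transition).
    """

    snp_id: str
    category: str
    beta: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown effect category {self.category!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the marginal structure of the study population:
    ΔC ≈ −18.4 ± 132.38 g, ΔF ≈ −4.71 ± 22.1 g, ΔTC ≈ −147 ± 759 kcal,
    Δbody fat ≈ −0.42 ± 2.57 kg, age ≈ 51 ± 8.5 y, and a ~0.4 per-wave
    exercise transition probability.
    """

    n_individuals: int = 1000
    n_snps: int = 20
    maf_range: tuple[float, float] = (0.05, 0.49)
    ld_block_size: int = 1          # 1 = independent SNPs
    ld_block_corr: float = 0.9      # within-block genotype correlation
    missing_rate: float = 0.0       # MCAR genotype missingness

    # dietary deltas (g/day) and the calorie link (kcal/day)
    dc_mean: float = -18.4
    dc_sd: float = 132.38
    df_mean: float = -4.71
    df_sd: float = 22.1
    tc_noise_sd: float = 506.0      # gives SD(ΔTC) ≈ 759 with the defaults

    # body-fat response (kg)
    intercept: float = -0.42
    gender_effect: float = 0.0
    age_effect: float = 0.0
    dc_effect: float = 0.0
    df_effect: float = 0.0
    dtc_effect: float = 0.0
    bodyfat_noise_sd: float = 2.57

    # covariates
    age_mean: float = 50.84
    age_sd: float = 8.54
    age_bounds: tuple[float, float] = (20.0, 90.0)
    female_prob: float = 0.5

    # baseline levels (two-wave diet study)
    carb_baseline_mean: float = 343.3
    carb_baseline_sd: float = 114.21
    fat_baseline_mean: float = 33.25
    fat_baseline_sd: float = 21.08
    kcal_baseline_mean: float = 1960.19
    kcal_baseline_sd: float = 688.77
    bodyfat_baseline_mean: float = 16.86
    bodyfat_baseline_sd: float = 5.29
    bmi_baseline_mean: float = 24.48
    bmi_baseline_sd: float = 3.0

    # exercise series
    transition_prob: float = 0.4
    initial_yes_prob: float = 0.5
    exercise_noise_sd: float = 2.2

    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        if self.n_snps <= 0:
            raise ValidationError("n_snps must be positive")
        for name in ("dc_sd", "df_sd", "tc_noise_sd", "bodyfat_noise_sd",
                     "exercise_noise_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("missing_rate", "transition_prob", "initial_yes_prob",
                     "female_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if not (0.0 <= self.ld_block_corr <= 1.0):
            raise ValidationError("ld_block_corr must lie in [0, 1]")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["age_bounds"] = list(self.age_bounds)
        d["effects"] = [asdict(e) for e in self.effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        d["effects"] = [EffectSpec(**e) for e in d.get("effects", [])]
        return cls(**d)

    def effects_for(self, category: str) -> list[EffectSpec]:
        return [e for e in self.effects if e.category == category]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _individual_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"I{i:0{width}d}" for i in range(1, n + 1)]


def generate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw additive minor-allele counts under Hardy-Weinberg equilibrium.

    Each SNP's MAF is drawn uniformly from ``config.maf_range`` and its
    count is the sum of two Bernoulli(maf) allele draws. With
    ``ld_block_size > 1`` consecutive SNPs form blocks sharing the seed
    SNP's MAF; each non-seed allele copies the seed allele with probability
    ``ld_block_corr`` and is redrawn independently otherwise, which makes
    the expected pairwise genotype correlation equal ``ld_block_corr``.
    """
    rng = _rng(config, _STREAM_GENO)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    block = config.ld_block_size
    alleles = np.empty((n, m, 2), dtype=np.int8)
    for j in range(m):
        if block > 1 and j % block != 0:
            seed_j = (j // block) * block
            mafs[j] = mafs[seed_j]
            keep = rng.random(size=(n, 2)) < config.ld_block_corr
            fresh = rng.random(size=(n, 2)) < mafs[j]
            alleles[:, j, :] = np.where(keep, alleles[:, seed_j, :], fresh)
        else:
            alleles[:, j, :] = rng.random(size=(n, 2)) < mafs[j]
    counts = alleles.sum(axis=2).astype(float)

    if config.missing_rate > 0:
        mask = rng.random(size=counts.shape) < config.missing_rate
        counts[mask] = np.nan

    snp_ids = [f"snp{j + 1:04d}" for j in range(m)]
    meta = pd.DataFrame(
        {"gene": "intergenic", "maf": mafs, "minor_allele": None},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    frame = pd.DataFrame(
        counts, index=pd.Index(_individual_ids(n), name="individual"), columns=snp_ids
    )
    return GenotypeMatrix(counts=frame, meta=meta)


def _covariates(config: SimConfig) -> pd.DataFrame:
    """Per-individual gender/age, shared by the diet and exercise series."""
    rng = _rng(config, _STREAM_COVAR)
    n = config.n_individuals
    gender = (rng.random(n) < config.female_prob).astype(float)
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    return pd.DataFrame(
        {"gender": gender, "age": age},
        index=pd.Index(_individual_ids(n), name="individual"),
    )


def _check_effects(config: SimConfig, genotypes: GenotypeMatrix) -> None:
    known = set(genotypes.snp_ids)
    for e in config.effects:
        if e.snp_id not in known:
            raise ValidationError(f"planted effect references unknown SNP {e.snp_id!r}")


def _filled_counts(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Counts with missing calls replaced by the expected count 2·maf."""
    expected = 2.0 * genotypes.meta["maf"]
    return genotypes.counts.fillna(expected)


def _lift_floor(baseline: np.ndarray, delta: np.ndarray, floor: float) -> np.ndarray:
    """Raise baselines just enough that baseline + delta stays >= floor.

    Keeps the drawn deltas exact while guaranteeing non-negative levels.
    """
    short = floor - (baseline + delta)
    return np.where(short > 0, baseline + short, baseline)


def generate_diet_outcomes(
    config: SimConfig, genotypes: GenotypeMatrix
) -> LongitudinalCohort:
    """Two-wave dietary study with planted gene-diet interaction effects.

    ΔC and ΔF are drawn from the configured normals; ΔTC = 4·ΔC + 9·ΔF plus
    independent noise. The body-fat change is the configured linear
    predictor — intercept, covariate and environmental main effects, SNP
    interaction terms from the planted CE/FE/TE effects — plus Gaussian
    noise. Baseline and follow-up levels are emitted as two survey waves
    whose differences equal the drawn deltas exactly.
    """
    _check_effects(config, genotypes)
    rng = _rng(config, _STREAM_DIET)
    n = config.n_individuals
    if n != len(genotypes.individuals):
        raise ValidationError("genotypes were generated for a different cohort size")
    cov = _covariates(config)

    d_c = rng.normal(config.dc_mean, config.dc_sd, n)
    d_f = rng.normal(config.df_mean, config.df_sd, n)
    d_tc = 4.0 * d_c + 9.0 * d_f + rng.normal(0.0, config.tc_noise_sd, n)

    filled = _filled_counts(genotypes)
    lp = (
        config.intercept
        + config.gender_effect * cov["gender"].to_numpy()
        + config.age_effect * cov["age"].to_numpy()
        + config.dc_effect * d_c
        + config.df_effect * d_f
        + config.dtc_effect * d_tc
    )
    env = {"CE": d_c, "FE": d_f, "TE": d_tc}
    for eff in config.effects:
        if eff.category == "EE":
            continue
        lp = lp + eff.beta * env[eff.category] * filled[eff.snp_id].to_numpy()
    d_bodyfat = lp + rng.normal(0.0, config.bodyfat_noise_sd, n)

    carb0 = np.clip(rng.normal(config.carb_baseline_mean, config.carb_baseline_sd, n), 1.0, None)
    fat0 = np.clip(rng.normal(config.fat_baseline_mean, config.fat_baseline_sd, n), 1.0, None)
    kcal0 = np.clip(rng.normal(config.kcal_baseline_mean, config.kcal_baseline_sd, n), 50.0, None)
    bf0 = np.clip(rng.normal(config.bodyfat_baseline_mean, config.bodyfat_baseline_sd, n), 2.0, None)
    bmi0 = np.clip(rng.normal(config.bmi_baseline_mean, config.bmi_baseline_sd, n), 12.0, None)
    d_bmi = rng.normal(-0.14, 1.2, n)

    carb0 = _lift_floor(carb0, d_c, 1.0)
    fat0 = _lift_floor(fat0, d_f, 1.0)
    kcal0 = _lift_floor(kcal0, d_tc, 50.0)
    bf0 = _lift_floor(bf0, d_bodyfat, 0.1)
    bmi0 = _lift_floor(bmi0, d_bmi, 12.0)

    ids = cov.index.to_numpy()
    rows = []
    for wave, (carb, fat, kcal, bf, bmi) in zip(
        DIET_WAVES,
        [
            (carb0, fat0, kcal0, bf0, bmi0),
            (carb0 + d_c, fat0 + d_f, kcal0 + d_tc, bf0 + d_bodyfat, bmi0 + d_bmi),
        ],
    ):
        rows.append(
            pd.DataFrame(
                {
                    "individual": ids,
                    "wave": wave,
                    "gender": cov["gender"].to_numpy(),
                    "age": cov["age"].to_numpy(),
                    "carb_g": carb,
                    "fat_g": fat,
                    "kcal": kcal,
                    "bodyfat_kg": bf,
                    "bmi": bmi,
                    "exercise": np.nan,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    return LongitudinalCohort(records=records)


def generate_exercise_series(
    config: SimConfig, genotypes: GenotypeMatrix
) -> LongitudinalCohort:
    """Five-wave exercise series with planted per-allele onset effects.

    Status evolves as a two-state chain (1 = not exercising, 2 = exercising)
    that flips with ``transition_prob`` at each wave step. Between waves the
    body fat increments by Gaussian noise; at an onset (1→2) the summed
    planted EE effect × allele count is added, at an offset (2→1) it is
    subtracted, so the oriented yes-minus-no difference recovers the planted
    effect.
    """
    _check_effects(config, genotypes)
    rng = _rng(config, _STREAM_EXER)
    n = config.n_individuals
    if n != len(genotypes.individuals):
        raise ValidationError("genotypes were generated for a different cohort size")
    cov = _covariates(config)
    waves = EXERCISE_WAVES
    k = len(waves)

    status = np.empty((n, k), dtype=int)
    status[:, 0] = np.where(rng.random(n) < config.initial_yes_prob, 2, 1)
    for t in range(1, k):
        flip = rng.random(n) < config.transition_prob
        status[:, t] = np.where(flip, 3 - status[:, t - 1], status[:, t - 1])

    filled = _filled_counts(genotypes)
    ee_effect = np.zeros(n)
    for eff in config.effects_for("EE"):
        ee_effect = ee_effect + eff.beta * filled[eff.snp_id].to_numpy()

    fat = np.empty((n, k))
    fat[:, 0] = np.clip(
        rng.normal(config.bodyfat_baseline_mean, config.bodyfat_baseline_sd, n), 2.0, None
    )
    for t in range(1, k):
        onset = (status[:, t - 1] == 1) & (status[:, t] == 2)
        offset = (status[:, t - 1] == 2) & (status[:, t] == 1)
        step = rng.normal(0.0, config.exercise_noise_sd, n)
        step = step + np.where(onset, ee_effect, 0.0) - np.where(offset, ee_effect, 0.0)
        fat[:, t] = fat[:, t - 1] + step
    # keep trajectories non-negative without disturbing any difference
    lift = np.clip(0.1 - fat.min(axis=1), 0.0, None)
    fat = fat + lift[:, None]

    ids = cov.index.to_numpy()
    rows = []
    for t, wave in enumerate(waves):
        rows.append(
            pd.DataFrame(
                {
                    "individual": ids,
                    "wave": wave,
                    "gender": cov["gender"].to_numpy(),
                    "age": cov["age"].to_numpy(),
                    "carb_g": np.nan,
                    "fat_g": np.nan,
                    "kcal": np.nan,
                    "bodyfat_kg": fat[:, t],
                    "bmi": np.nan,
                    "exercise": status[:, t].astype(float),
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    return LongitudinalCohort(records=records)
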