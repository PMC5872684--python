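"""End-to-end orchestration: simulate-or-load → derive → screen → prune →
score → classify → evaluate, with seeded determinism and a run manifest.

Every artifact is a plain TSV in the output directory; the manifest records
the seed, a hash of the effective configuration and per-stage row counts,
and re-running with an identical configuration reproduces byte-identical
outputs. The diet and exercise analyses run on separate (overlapping)
sub-cohorts selected by data availability, as in a survey cohort where the
dietary questionnaire and the exercise question cover different waves.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .containers import CATEGORIES, CategorySelection, GenotypeMatrix, LongitudinalCohort
from .evaluate import (
    grs_descriptives,
    group_means,
    responder_subset,
    trend_statistic,
)
from .grs import assign_signs, build_profiles
from .ld import ld_edges, prune_by_ld
from .phenotypes import compute_diet_deltas, compute_exercise_delta
from .screen import screen_panel, select_snps
from .simulate import SimConfig, generate_diet_outcomes, generate_exercise_series, generate_genotypes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is either "simulate" (generate the cohort from ``sim``) or
    "load" (read the three input tables from ``paths``: keys ``genotypes``,
    ``cohort_diet``, ``cohort_exercise`` and optionally ``panel``).
    """

    mode: str = "simulate"
    sim: SimConfig = field(default_factory=SimConfig)
    paths: dict = field(default_factory=dict)
    alpha: float = 0.05
    ld_threshold: float = 0.7
    percentile_method: str = "linear"
    baseline_wave: int = 0
    followup_wave: int = 3
    min_carriers: int = 5
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "simulate":
            # the run seed governs the generator
            self.sim.seed = self.seed

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sim": self.sim.to_dict(),
            "paths": dict(self.paths),
            "alpha": self.alpha,
            "ld_threshold": self.ld_threshold,
            "percentile_method": self.percentile_method,
            "baseline_wave": self.baseline_wave,
            "followup_wave": self.followup_wave,
            "min_carriers": self.min_carriers,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(table: pd.DataFrame, path: Path, *, index: bool = False) -> int:
    """Write a (possibly empty) stage artifact deterministically."""
    if len(table) == 0:
        # header-only file; an empty stage is legitimate (e.g. alpha = 0)
        table.to_csv(path, sep="\t", na_rep="NA", index=index)
        logger.warning("stage wrote an empty table: %s", path.name)
    else:
        table.to_csv(path, sep="\t", na_rep="NA", index=index)
    return len(table)


def fits_to_table(fits) -> pd.DataFrame:
    """Flatten FitResults to one row per (snp, model, term)."""
    rows = []
    for fr in fits:
        target_terms = set(fr.targets.values())
        for term, row in fr.fit.params.iterrows():
            rows.append(
                {
                    "snp_id": fr.snp_id,
                    "model": fr.model,
                    "term": term,
                    "coef": row["coef"],
                    "se": row["se"],
                    "p": row["p"],
                    "n": fr.fit.n_used,
                    "is_target": term in target_terms,
                }
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "model", "term", "coef", "se", "p", "n", "is_target"]
    )


def selections_to_table(selections: dict[str, CategorySelection]) -> pd.DataFrame:
    frames = []
    for category in CATEGORIES:
        sel = selections.get(category)
        if sel is None:
            continue
        frames.append(sel.table.assign(category=category))
    if not frames:
        return pd.DataFrame(columns=["category", "snp_id", "coef", "p", "sign"])
    out = pd.concat(frames, ignore_index=True)
    return out[["category", "snp_id", "coef", "p", "sign"]]


def table_to_selections(table: pd.DataFrame) -> dict[str, CategorySelection]:
    out = {}
    for category in CATEGORIES:
        sub = table[table["category"] == category]
        out[category] = CategorySelection(
            category=category,
            table=sub[["snp_id", "coef", "p", "sign"]].reset_index(drop=True),
        )
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Any stage failure raises with the stage name prepended so a caller can
    report where the run died.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "files": {},
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- inputs -----------------------------------------------------------
    if config.mode == "simulate":
        genotypes = stage("simulate")(generate_genotypes, config.sim)
        cohort_diet = stage("simulate")(generate_diet_outcomes, config.sim, genotypes)
        cohort_exer = stage("simulate")(generate_exercise_series, config.sim, genotypes)
    else:
        panel = (
            gio.read_panel(config.paths["panel"]) if "panel" in config.paths else None
        )
        genotypes = stage("load")(gio.read_genotypes, config.paths["genotypes"], panel)
        cohort_diet = stage("load")(gio.read_cohort, config.paths["cohort_diet"])
        cohort_exer = stage("load")(gio.read_cohort, config.paths["cohort_exercise"])

    gio.write_genotypes(genotypes, outdir / "genotypes.tsv")
    gio.write_cohort(cohort_diet, outdir / "cohort_diet.tsv")
    gio.write_cohort(cohort_exer, outdir / "cohort_exercise.tsv")
    panel_table = genotypes.meta.reset_index()[["snp_id", "gene", "maf"]]
    _write(panel_table, outdir / "panel.tsv")
    manifest["stages"]["input"] = {
        "n_individuals": len(genotypes.individuals),
        "n_snps": len(genotypes.snp_ids),
        "n_missing_genotypes": genotypes.n_missing,
    }

    # --- derive -----------------------------------------------------------
    diet_deltas = stage("derive")(
        compute_diet_deltas, cohort_diet, config.baseline_wave, config.followup_wave
    )
    exer_deltas = stage("derive")(compute_exercise_delta, cohort_exer)
    _write(diet_deltas.reset_index(), outdir / "deltas_diet.tsv")
    _write(exer_deltas.reset_index(), outdir / "deltas_exercise.tsv")
    manifest["stages"]["derive"] = {
        "n_diet": len(diet_deltas),
        "n_diet_excluded": diet_deltas.attrs.get("n_excluded", 0),
        "n_exercise": len(exer_deltas),
    }

    # --- screen -----------------------------------------------------------
    fits, skip_log = stage("screen")(
        screen_panel, diet_deltas, exer_deltas, genotypes, config.min_carriers
    )
    selections = stage("screen")(select_snps, fits, config.alpha)
    _write(fits_to_table(fits), outdir / "fits.tsv")
    _write(skip_log, outdir / "skipped_snps.tsv")
    _write(selections_to_table(selections), outdir / "selections.tsv")
    manifest["stages"]["screen"] = {
        "n_snps_tested": len({f.snp_id for f in fits}),
        "n_skipped": len(skip_log),
        "n_selected": {c: len(selections[c]) for c in CATEGORIES},
    }

    # --- prune ------------------------------------------------------------
    pruned: dict[str, CategorySelection] = {}
    edge_frames = []
    for category in CATEGORIES:
        sel = selections[category]
        edges = ld_edges(genotypes, sel.snp_ids, config.ld_threshold)
        edge_frames.append(edges.assign(category=category))
        pruned[category] = stage("prune")(
            prune_by_ld, sel, genotypes, config.ld_threshold
        )
    edges_all = pd.concat(edge_frames, ignore_index=True)
    _write(
        edges_all[["category", "snp_a", "snp_b", "r2"]]
        if len(edges_all)
        else pd.DataFrame(columns=["category", "snp_a", "snp_b", "r2"]),
        outdir / "ld_edges.tsv",
    )
    manifest["stages"]["prune"] = {
        "n_retained": {c: len(pruned[c]) for c in CATEGORIES},
        "n_removed": {c: len(selections[c]) - len(pruned[c]) for c in CATEGORIES},
    }

    # --- score & classify -------------------------------------------------
    signed = {c: stage("score")(assign_signs, pruned[c]) for c in CATEGORIES}
    _write(selections_to_table(signed), outdir / "weights.tsv")
    profiles, cuts = stage("classify")(
        build_profiles, genotypes, signed, config.percentile_method
    )
    _write(profiles.reset_index(), outdir / "profiles.tsv")
    cuts_table = pd.DataFrame(
        [
            {"category": c, "q25": cuts[c].q25, "q50": cuts[c].q50, "q75": cuts[c].q75}
            for c in CATEGORIES
        ]
    )
    _write(cuts_table, outdir / "cutpoints.tsv")
    manifest["stages"]["score"] = {
        "n_profiled": len(profiles),
    }

    # --- evaluate ---------------------------------------------------------
    summaries = []
    trends = []
    for category in CATEGORIES:
        if len(signed[category]) == 0:
            continue
        deltas = exer_deltas if category == "EE" else diet_deltas
        if len(deltas) == 0:
            continue
        subset = responder_subset(deltas, category)
        if len(subset) == 0:
            continue
        summaries.append(
            stage("evaluate")(group_means, subset, profiles, deltas, category)
        )
        try:
            slope, p = trend_statistic(subset, profiles, deltas, category)
            trends.append({"category": category, "slope": slope, "p": p})
        except Exception:
            logger.warning("trend not computable for %s", category)
    report = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=["category", "class", "n", "mean", "sd"])
    )
    _write(report, outdir / "class_summaries.tsv")
    _write(
        pd.DataFrame(trends, columns=["category", "slope", "p"]),
        outdir / "trends.tsv",
    )
    grs_vectors = {
        c: profiles[f"{c}_grs"] for c in CATEGORIES if len(signed[c]) > 0
    }
    if grs_vectors:
        descriptives = stage("evaluate")(
            grs_descriptives, grs_vectors, 5000, config.seed
        )
    else:
        descriptives = pd.DataFrame(
            columns=["category", "n", "mean", "sd", "median", "min", "max", "shapiro_p"]
        )
    _write(descriptives, outdir / "grs_descriptives.tsv")
    manifest["stages"]["evaluate"] = {
        "n_summary_rows": len(report),
        "n_trends": len(trends),
    }

    manifest["files"] = sorted(p.name for p in outdir.glob("*.tsv"))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
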