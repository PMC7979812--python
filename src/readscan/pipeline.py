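"""End-to-end orchestration: simulate -> clean -> map -> classify -> metrics
-> similarity -> compare, with deterministic seeding and exclusion
accounting."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .event_io import DisplayGeometry, TrialRecord, write_event_report
from .group_stats import SIGN_CONVENTION, hedges_g_from_values
from .interest_mapping import (assign_fixations, build_interest_areas,
                               correct_vertical_drift)
from .layout import TextLayout
from .preprocess import CleaningConfig, CleaningReport, clean_trial
from .reading_metrics import (METRIC_COLUMNS, normalize_profile,
                              trial_metrics)
from .saccade_taxonomy import TaxonomyConfig, classify_saccades
from .scanpath_similarity import (AssociationResult, ClusterResult,
                                  ScasimConfig, association_test,
                                  embed_and_cluster, scasim_matrix)
from .synthetic_data import CohortSpec, simulate_cohort

# metrics entering the group effect-size profile (reading_duration is the
# GLMM response, not an effect-size row)
PROFILE_METRICS = [m for m in METRIC_COLUMNS if m != "reading_duration"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    drift_mode: str = "off"
    scasim_modulator: float = 0.83
    scasim_normalize: bool = True
    k_max: int = 9
    run_similarity: bool = True
    seed: int = 0


@dataclass
class PairResult:
    text_id: str
    font: str
    cluster: ClusterResult
    association: AssociationResult


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame
    effect_table: pd.DataFrame
    cleaning_reports: dict[str, CleaningReport]
    excluded_trials: list[str]
    pairs: list[PairResult]
    profile_means: pd.DataFrame | None
    profile_excluded: list[str]

    @property
    def significant_pair_fraction(self) -> float:
        tested = [p for p in self.pairs
                  if p.association.method != "undefined"]
        if not self.pairs:
            return float("nan")
        hits = sum(1 for p in tested if p.association.p < 0.05)
        return hits / len(self.pairs)


def effect_size_table(metrics: pd.DataFrame,
                      columns: Sequence[str] = PROFILE_METRICS,
                      group_column: str = "group") -> pd.DataFrame:
    """Hedges' g (control minus dyslexia) per metric over all trials."""
    groups = sorted(metrics[group_column].unique())
    if len(groups) != 2:
        raise ValueError("effect table requires exactly two groups")
    g1 = "control" if "control" in groups else groups[0]
    g2 = [g for g in groups if g != g1][0]
    rows = []
    for col in columns:
        a = metrics.loc[metrics[group_column] == g1, col].dropna()
        b = metrics.loc[metrics[group_column] == g2, col].dropna()
        if len(a) < 2 or len(b) < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
            continue
        res = hedges_g_from_values(a, b)
        rows.append({
            "metric": col, "g": res.g,
            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "n1": res.n1, "n2": res.n2,
            "significant": res.significant,
        })
    table = pd.DataFrame(rows)
    table.attrs["sign_convention"] = SIGN_CONVENTION
    return table


def analyze_cohort(
    trials: Sequence[TrialRecord],
    layouts: dict[tuple[str, str], TextLayout],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run cleaning, mapping, classification, metrics, similarity and the
    group comparison over an in-memory cohort."""
    config = config or PipelineConfig()
    areas_cache = {key: build_interest_areas(layout)
                   for key, layout in layouts.items()}

    rows = []
    cleaned_by_pair: dict[tuple[str, str], list[TrialRecord]] = {}
    reports: dict[str, CleaningReport] = {}
    excluded: list[str] = []
    for trial in trials:
        key = (trial.text_id, trial.font)
        layout = layouts[key]
        areas = areas_cache[key]
        cleaned, report = clean_trial(trial, config.cleaning)
        reports[trial.trial_id] = report
        if cleaned.excluded or not cleaned.fixations:
            excluded.append(trial.trial_id)
            continue
        if config.drift_mode != "off":
            cleaned, _ = correct_vertical_drift(cleaned, areas,
                                                mode=config.drift_mode)
        assigned = assign_fixations(cleaned, areas)
        labels = classify_saccades(cleaned, assigned, layout, config.taxonomy)
        tm = trial_metrics(cleaned, assigned, layout, config.taxonomy,
                           labels=labels)
        rows.append({
            "trial_id": trial.trial_id,
            "participant": trial.participant_id,
            "group": trial.group, "font": trial.font, "text": trial.text_id,
            **tm.to_dict(),
        })
        cleaned_by_pair.setdefault(key, []).append(cleaned)

    metrics = pd.DataFrame(rows)
    effect_table = effect_size_table(metrics)

    pairs: list[PairResult] = []
    if config.run_similarity:
        sc = ScasimConfig(modulator=config.scasim_modulator,
                          normalize=config.scasim_normalize,
                          geometry=trials[0].geometry if trials
                          else DisplayGeometry())
        for key in sorted(cleaned_by_pair):
            group_trials = cleaned_by_pair[key]
            if len(group_trials) < 4:
                continue
            sim = scasim_matrix(group_trials, sc)
            cluster = embed_and_cluster(sim, k_max=config.k_max,
                                        seed=config.seed)
            assoc = association_test(
                cluster.assignments, [t.group for t in group_trials])
            pairs.append(PairResult(key[0], key[1], cluster, assoc))

    try:
        _, profile_means, profile_excluded = normalize_profile(
            metrics, [c for c in PROFILE_METRICS
                      if metrics[c].notna().all()])
    except ValueError:
        profile_means, profile_excluded = None, []

    return AnalysisResult(
        metrics=metrics, effect_table=effect_table,
        cleaning_reports=reports, excluded_trials=excluded,
        pairs=pairs, profile_means=profile_means,
        profile_excluded=profile_excluded,
    )


# ---------------------------------------------------------------------------
# file-emitting runner
# ---------------------------------------------------------------------------

def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items(),
                                                      key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate the configured cohort, analyze it, and write all artifacts.

    Emits: events TSV, per-trial metrics TSV, effect-size table TSV,
    similarity/cluster JSON, group-profile JSON and a run manifest with the
    config hash and per-artifact checksums (deterministic given the seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.cohort, master_seed=config.seed)
    trials, layouts = simulate_cohort(spec)
    result = analyze_cohort(trials, layouts, config)

    events_path = outdir / "events.tsv"
    write_event_report(trials, events_path)
    metrics_path = outdir / "trial_metrics.tsv"
    result.metrics.to_csv(metrics_path, sep="\t", index=False,
                          float_format="%.6g")
    effects_path = outdir / "effect_sizes.tsv"
    result.effect_table.to_csv(effects_path, sep="\t", index=False,
                               float_format="%.6g")
    similarity_path = outdir / "similarity.json"
    similarity_path.write_text(json.dumps({
        "pairs": [
            {
                "text": p.text_id, "font": p.font, "k": p.cluster.k,
                "stress": p.cluster.stress,
                "assignments": p.cluster.assignments.tolist(),
                "method": p.association.method,
                "p": None if np.isnan(p.association.p) else p.association.p,
                "table": p.association.table.tolist(),
            }
            for p in result.pairs
        ],
        "significant_fraction": result.significant_pair_fraction,
    }, indent=1))
    profile_path = outdir / "group_profile.json"
    profile_path.write_text(json.dumps({
        "schema": 1,
        "z_group_means": (result.profile_means.to_dict()
                          if result.profile_means is not None else {}),
        "excluded_metrics": result.profile_excluded,
    }, indent=1))

    artifacts = [events_path, metrics_path, effects_path,
                 similarity_path, profile_path]
    manifest = {
        "schema": 1,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_trials_input": len(trials),
        "n_trials_analyzed": len(result.metrics),
        "n_trials_excluded": len(result.excluded_trials),
        "excluded_trials": result.excluded_trials,
        "checksums": {p.name: _checksum(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def export_report(result: AnalysisResult, outdir: str | Path,
                  fmt: str = "tsv") -> list[Path]:
    """Serialize the analysis tables in the requested format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        paths = [outdir / "trial_metrics.tsv", outdir / "effect_sizes.tsv"]
        result.metrics.to_csv(paths[0], sep="\t", index=False,
                              float_format="%.6g")
        result.effect_table.to_csv(paths[1], sep="\t", index=False,
                                   float_format="%.6g")
        return paths
    if fmt == "json":
        path = outdir / "analysis.json"
        path.write_text(json.dumps({
            "schema": 1,
            "metrics": result.metrics.to_dict(orient="records"),
            "effects": result.effect_table.to_dict(orient="records"),
        }, indent=1))
        return [path]
    raise ValueError(f"unknown format {fmt!r}")
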