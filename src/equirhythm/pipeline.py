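"""End-to-end orchestration: simulate -> analyze -> summarize -> cohort.

Every run writes a manifest with the echoed configuration, the seed and a
SHA-256 checksum per output file, so identical (config, seed) runs can be
verified to reproduce byte-identical artefacts (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import (
    read_tachogram,
    read_workout_metadata,
    write_tachogram,
    write_workout_metadata,
)
from .cohort import (
    DegenerateModelError,
    build_group_summary,
    fit_mixed_logistic,
    fit_mixed_poisson,
    spearman,
    summary_to_frame,
)
from .rhythm import analyze_tachogram
from .simulate import simulate_cohort
from .summary import read_results, summarize_workout, write_results

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    seed: int
    format_version: str = FORMAT_VERSION
    package_version: str = __version__
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None
    started_at: str = ""
    finished_at: str = ""

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(outputs)
                },
            }
        )

    def checksums(self) -> dict:
        """Stage-to-checksum mapping (the deterministic part)."""
        return {s["stage"]: s["outputs"] for s in self.stages}

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "format_version": self.format_version,
            "package_version": self.package_version,
            "stages": self.stages,
            "failed_stage": self.failed_stage,
            "started_at": self.started_at,
            "finished_at": self.finished_at,
        }


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))


def _analysis_kwargs(config: PipelineConfig) -> dict:
    return dict(
        threshold=config.detection.threshold,
        window=config.detection.window,
        statistic=config.detection.reference_statistic,
        threshold_mode=config.detection.threshold_mode,
        pause_tolerance=config.pause.tolerance,
        paf_min_beats=config.paf.min_beats,
        paf_cv_threshold=config.paf.cv_threshold,
        decel_drop_bpm=config.deceleration.drop_bpm,
        decel_window_s=config.deceleration.window_s,
        decel_smooth_s=config.deceleration.smooth_s,
        decel_min_peak_bpm=config.deceleration.min_peak_bpm,
    )


def stage_simulate(config: PipelineConfig, out_dir: Path) -> list[Path]:
    if config.simulation is None:
        raise PipelineError("no simulation block in configuration")
    sim = config.simulation.model_copy(update={"seed": config.seed})
    tach_dir = out_dir / "tachograms"
    tach_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    metas = []
    for _, plan, tach, truth in simulate_cohort(sim):
        tach_path = tach_dir / f"{plan.workout_id}.csv"
        write_tachogram(tach, tach_path)
        truth_path = tach_dir / f"{plan.workout_id}.truth.json"
        truth_path.write_text(truth.to_json())
        outputs += [tach_path, truth_path]
        metas.append(tach.meta)
        logger.info("simulate: %s (%d beats, %d injected events)",
                    plan.workout_id, tach.n_beats, len(truth.ledger))
    meta_path = out_dir / "cohort_metadata.csv"
    write_workout_metadata(metas, meta_path)
    outputs.append(meta_path)
    return outputs


def stage_analyze(
    config: PipelineConfig, tachogram_dir: Path, metadata_csv: Path, out_dir: Path
) -> list[Path]:
    metas = read_workout_metadata(metadata_csv)
    analysis_dir = out_dir / "analysis"
    analysis_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    results = []
    kwargs = _analysis_kwargs(config)
    for csv_path in sorted(tachogram_dir.glob("*.csv")):
        workout_id = csv_path.stem
        meta = metas.get(workout_id)
        tach = read_tachogram(csv_path, meta=meta)
        analysis = analyze_tachogram(tach, **kwargs)
        events_path = analysis_dir / f"{workout_id}.events.json"
        events_path.write_text(
            json.dumps([e.to_dict() for e in analysis.events], indent=1)
        )
        profile_path = analysis_dir / f"{workout_id}.profile.json"
        profile_path.write_text(json.dumps(analysis.profile.to_dict(), indent=1))
        outputs += [events_path, profile_path]
        logger.info("analyze: %s -> %d events, nPC=%d",
                    workout_id, len(analysis.events), analysis.profile.n_pc)
        if meta is not None:
            results.append(
                summarize_workout(
                    tach,
                    analysis.profile,
                    analysis.labels,
                    meta,
                    inclusion_cutoff=config.readability.inclusion_cutoff,
                    readability_weighting=config.readability.weighting,
                    hr_mean_exclude_artifact=config.hr.mean_exclude_artifact,
                )
            )
    results_path = out_dir / "workout_results.csv"
    write_results(results, results_path)
    outputs.append(results_path)
    return outputs


def stage_cohort(config: PipelineConfig, results_csv: Path, out_dir: Path) -> list[Path]:
    results = read_results(results_csv)
    outputs: list[Path] = []

    summary = summary_to_frame(build_group_summary(results))
    summary_path = out_dir / "group_summary.csv"
    summary.to_csv(summary_path, index=False)
    outputs.append(summary_path)

    included = results[results["included"].astype(bool)]
    assoc_rows = []
    for x_name, y_name in config.models.association_pairs:
        try:
            assoc_rows.append(
                spearman(included[x_name], included[y_name], x_name, y_name).to_dict()
            )
        except ValueError as exc:
            assoc_rows.append(
                {"x_name": x_name, "y_name": y_name, "rho": None,
                 "p_value": None, "band": None, "n": len(included),
                 "error": str(exc)}
            )
    assoc_path = out_dir / "associations.csv"
    pd.DataFrame(assoc_rows).to_csv(assoc_path, index=False)
    outputs.append(assoc_path)

    models = {}
    for outcome in config.models.logistic_outcomes:
        try:
            models[outcome] = fit_mixed_logistic(
                included, outcome, config.models.fixed_terms
            ).to_dict()
        except (DegenerateModelError, ValueError) as exc:
            models[outcome] = {"error": str(exc)}
    try:
        models[config.models.poisson_outcome] = fit_mixed_poisson(
            included, config.models.poisson_outcome, config.models.fixed_terms
        ).to_dict()
    except (DegenerateModelError, ValueError) as exc:
        models[config.models.poisson_outcome] = {"error": str(exc)}
    models_path = out_dir / "models.json"
    models_path.write_text(json.dumps(models, indent=1, sort_keys=True))
    outputs.append(models_path)
    return outputs


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    tachogram_dir: str | Path | None = None,
    metadata_csv: str | Path | None = None,
) -> RunManifest:
    """Run all stages; simulation is skipped when external inputs are given.

    Raises before any stage runs when required input paths are missing.
    On a stage failure, partial outputs are kept and the manifest records
    the failure point.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        seed=config.seed,
        started_at=datetime.now(timezone.utc).isoformat(),
    )

    simulate = tachogram_dir is None
    if simulate and config.simulation is None:
        raise PipelineError(
            "either a simulation block or an input tachogram directory is required"
        )
    if not simulate:
        tachogram_dir = Path(tachogram_dir)
        metadata_csv = Path(metadata_csv) if metadata_csv else tachogram_dir / "cohort_metadata.csv"
        for required in (tachogram_dir, metadata_csv):
            if not Path(required).exists():
                raise PipelineError(f"missing input path: {required}")

    try:
        if simulate:
            manifest.record("simulate", stage_simulate(config, out))
            tachogram_dir = out / "tachograms"
            metadata_csv = out / "cohort_metadata.csv"
        manifest.record(
            "analyze", stage_analyze(config, Path(tachogram_dir), Path(metadata_csv), out)
        )
        manifest.record("cohort", stage_cohort(config, out / "workout_results.csv", out))
    except Exception as exc:
        stage_names = {s["stage"] for s in manifest.stages}
        for name in ("simulate", "analyze", "cohort"):
            if name not in stage_names:
                manifest.failed_stage = name
                break
        manifest.finished_at = datetime.now(timezone.utc).isoformat()
        write_manifest(manifest, out / "manifest.json")
        raise PipelineError(f"stage {manifest.failed_stage!r} failed: {exc}") from exc

    manifest.finished_at = datetime.now(timezone.utc).isoformat()
    write_manifest(manifest, out / "manifest.json")
    return manifest
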