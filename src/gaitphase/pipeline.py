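"""End-to-end orchestration: simulate -> segment -> parameters -> turning ->
cluster -> aggregate -> validate, with a reproducible manifest.

Every stage communicates through plain CSV/JSON files (or in-memory objects
when run as a library), so each stage can also be run standalone through the
CLI.  All randomness derives from one global seed; a rerun with the same
configuration produces byte-identical result files and manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, clustering, segmentation, turning as turning_mod, validation
from .core import GaitClusterSet, GaitError, StrideRecord
from .io import write_imu_csv, write_subjects_csv
from .parameters import extract_stride_records
from .synthetic import CohortSpec, SyntheticRecording, generate_cohort, synthesize_imu

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("10%crop", "25%crop", "median t", "distr vel", "3means vel", "perc vel")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gaitphase_out"
    n_subjects: int = 12
    impaired_fraction: float = 0.5
    velocity_shift: float = 0.15
    cv_multiplier: float = 2.0
    extra_turn_strides: int = 1
    noise_sd: float = 1.0
    sampling_rate: float = 102.4
    methods: tuple = DEFAULT_METHODS
    targets: tuple = ("gait",)
    distance_threshold: float = segmentation.DEFAULT_DISTANCE_THRESHOLD
    refine_radius: int = 10
    tail_q: float = 0.9
    hard_threshold_deg: float = 20.0
    validate: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GaitError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "targets"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        d["targets"] = list(d["targets"])
        return d


@dataclass
class SubjectAnalysis:
    """Merged, time-ordered stride records of both feet plus turning info."""

    records: list[StrideRecord]
    turning_flags: np.ndarray
    turns: list[turning_mod.Turn]
    bouts: list[clustering.Bout]


def analyze_recording(
    synth: SyntheticRecording,
    height_cm: float,
    distance_threshold: float = segmentation.DEFAULT_DISTANCE_THRESHOLD,
    refine_radius: int = 10,
    tail_q: float = 0.9,
    hard_threshold_deg: float = 20.0,
    use_truth_segments: bool = False,
) -> SubjectAnalysis:
    """Run segmentation, parameter extraction and turning isolation on one
    recording; merge both feet by stride start time."""
    per_foot_records: list[list[StrideRecord]] = []
    per_foot_flags: list[np.ndarray] = []
    turns: list[turning_mod.Turn] = []
    for rec in (synth.left, synth.right):
        if use_truth_segments:
            segments = synth.segments[rec.foot]
        else:
            template = segmentation.canonical_template(
                int(round(np.median(synth.schedule.stride_times) * rec.sampling_rate))
            )
            segments = segmentation.dtw_segment(
                rec.gz, template, distance_threshold, foot=rec.foot
            )
            segments = segmentation.refine_by_minima(rec.gz, segments, refine_radius)
        records = extract_stride_records(rec, segments, height_cm)
        tas = [r.turning_angle for r in records]
        times = [r.stride_time for r in records]
        result = turning_mod.isolate_turning(
            tas, q=tail_q, hard_threshold_deg=hard_threshold_deg, stride_times=times
        )
        turns.extend(result.turns)
        per_foot_records.append(records)
        per_foot_flags.append(result.is_turning)

    merged = []
    for records, flags in zip(per_foot_records, per_foot_flags):
        merged.extend(zip(records, flags))
    merged.sort(key=lambda rf: (rf[0].start_time, rf[0].foot))
    records = [r for r, _ in merged]
    flags = np.array([f for _, f in merged], dtype=bool)
    bouts = clustering.split_into_bouts(len(records), flags)
    return SubjectAnalysis(records=records, turning_flags=flags, turns=turns, bouts=bouts)


def label_strides(analysis: SubjectAnalysis, method: str, seed: int = 0) -> list[StrideRecord]:
    """Final per-stride labels for one clustering method (turning strides keep
    the turning label); the partition invariant is asserted."""
    records = [replace_label(r, "turning" if f else "unassigned") for r, f in
               zip(analysis.records, analysis.turning_flags)]
    for bout in analysis.bouts:
        vel = [analysis.records[i].stride_velocity for i in bout.stride_indices]
        times = [analysis.records[i].stride_time for i in bout.stride_indices]
        try:
            labels = clustering.cluster_bout(vel, times, method, seed=seed)
        except GaitError:
            # bouts too small for the method (e.g. 1-2 stride fragments
            # between turns) are transition strides: raw non-constant
            labels = clustering.postprocess_labels(np.ones(len(vel), dtype=bool))
        for idx, lab in zip(bout.stride_indices, labels):
            records[idx] = replace_label(records[idx], lab, bout.bout_id)
    GaitClusterSet(records)  # raises if any stride escaped labeling
    return records


def replace_label(record: StrideRecord, label: str, bout_id: int | None = None) -> StrideRecord:
    return dataclasses.replace(record, label=label, bout_id=bout_id)


def cohort_features(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list, dict]:
    """Simulate a cohort and compute per-subject features for every cluster
    and method.  Returns (long feature table, subjects, analyses-by-subject)."""
    spec = CohortSpec(
        n_subjects=config.n_subjects,
        impaired_fraction=config.impaired_fraction,
        velocity_shift=config.velocity_shift,
        cv_multiplier=config.cv_multiplier,
        extra_turn_strides=config.extra_turn_strides,
        seed=config.seed,
    )
    schedules, subjects = generate_cohort(spec)
    synth_seeds = np.random.SeedSequence(config.seed).spawn(len(subjects))

    rows = []
    analyses = {}
    for i, (schedule, subject) in enumerate(zip(schedules, subjects)):
        synth = synthesize_imu(
            schedule,
            sampling_rate=config.sampling_rate,
            noise_sd=config.noise_sd,
            seed=synth_seeds[i],
        )
        analysis = analyze_recording(
            synth,
            subject.height,
            distance_threshold=config.distance_threshold,
            refine_radius=config.refine_radius,
            tail_q=config.tail_q,
            hard_threshold_deg=config.hard_threshold_deg,
        )
        analyses[subject.subject_id] = analysis
        for method in config.methods:
            labeled = label_strides(analysis, method, seed=config.seed)
            feats = aggregation.subject_feature_row(labeled, analysis.turns)
            for cluster, values in feats.items():
                row = {"subject_id": subject.subject_id, "method": method, "cluster": cluster}
                row.update(values)
                rows.append(row)
    return pd.DataFrame(rows), subjects, analyses


def _feature_matrix(table: pd.DataFrame, cluster: str, method: str, subjects) -> pd.DataFrame:
    sub = table[(table.cluster == cluster) & (table.method == method)]
    sub = sub.set_index("subject_id").drop(columns=["method", "cluster"])
    return sub.reindex([s.subject_id for s in subjects])


def run_validations(table: pd.DataFrame, subjects, config: PipelineConfig) -> pd.DataFrame:
    """Validate every cluster x method (baseline and turning once per method
    set, since they do not depend on the clustering method)."""
    rows = []
    ref_method = config.methods[0]
    for target in config.targets:
        scores = [
            s.gait_score if target == "gait" else s.postural_stability_score for s in subjects
        ]
        vconfig = validation.ValidationConfig(target=target, seed=config.seed)
        tasks = [("baseline", ref_method, "baseline"), ("turning", ref_method, "turning")]
        for method in config.methods:
            tasks.append(("constant", method, method))
            tasks.append(("non_constant", method, method))
        for cluster, method, method_label in tasks:
            feats = _feature_matrix(table, cluster, method, subjects)
            result = validation.run_validation(feats, scores, cluster, method_label, vconfig)
            rows.append(
                {
                    "target": target,
                    "cluster": cluster,
                    "method": method_label,
                    "test_auc": result.test_auc,
                    "cv_auc": result.cv_auc,
                    "best_c": result.best_c,
                    "best_gamma": result.best_gamma,
                    "selected_features": ";".join(result.selected_features),
                }
            )
    return pd.DataFrame(rows)


def report(results: pd.DataFrame) -> pd.DataFrame:
    """AUC per cluster/method with relative change vs baseline (percent)."""
    if "baseline" not in set(results.cluster):
        raise GaitError("results contain no baseline rows")
    out = []
    for target, group in results.groupby("target"):
        base = group[group.cluster == "baseline"]["test_auc"].iloc[0]
        for _, row in group.iterrows():
            out.append(
                {
                    "target": target,
                    "cluster": row.cluster,
                    "method": row.method,
                    "test_auc": row.test_auc,
                    "baseline_auc": base,
                    "relative_change_pct": round((row.test_auc - base) / base * 100.0, 1),
                }
            )
    return pd.DataFrame(out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write results plus a manifest to out_dir.

    Returns the manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "files": {}}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            _write_manifest(out, manifest)
            raise
        logger.info("stage %s finished in %.3f s", name, time.perf_counter() - t0)
        manifest["stages"].append({"name": name, "status": "ok"})
        return result

    table, subjects, analyses = _stage("simulate+features", lambda: cohort_features(config))

    write_subjects_csv(subjects, out / "subjects.csv")
    table.to_csv(out / "features.csv", index=False, float_format="%.10g")
    stride_counts = {sid: len(a.records) for sid, a in analyses.items()}
    logger.info("processed %d subjects, %s strides total", len(subjects), sum(stride_counts.values()))

    if config.validate:
        results = _stage("validate", lambda: run_validations(table, subjects, config))
        results.to_csv(out / "results.csv", index=False, float_format="%.10g")
        summary = report(results)
        summary.to_csv(out / "report.csv", index=False, float_format="%.10g")

    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
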