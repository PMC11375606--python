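"""End-to-end orchestration: read -> segment-check -> metrics -> gaze -> stats.

A run consumes a directory of transcript YAMLs, one fixation report
TSV (trial labels ``<participant>__<picture>``), and AOI configs
(packaged synthetic polygons by default), and emits a metrics CSV, an
ANOVA report, and a manifest recording the configuration hash and
package version. Identical config + inputs give byte-identical
outputs. Any stage error aborts with the stage name and the offending
record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from .gaze import MEMBERSHIP_MODES, assign_fixations, prespeech_metrics
from .io import (
    packaged_aoi_config,
    read_aoi_config,
    read_fixation_report,
    read_transcript,
    write_aoi_config,
    write_fixation_report,
    write_metrics_csv,
    write_transcript,
)
from .metrics import compute_metrics_row
from .segmentation import SegmentationConfig, boundary_diff, segment_utterances
from .stats import melt_pos, mixed_anova, two_sample_t
from .types import PICTURES, MetricsRow, TrialRecord

logger = logging.getLogger("prespeech")

ANOVA_SPECS = [
    ("cius_per_min", ["picture_id"], None),
    ("nv_token", ["picture_id", "pos"], "token"),
    ("nv_type", ["picture_id", "pos"], "type"),
    ("prespeech_count_per_utt", ["picture_id"], None),
    ("prespeech_dur_per_utt", ["picture_id"], None),
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    transcripts_dir: str
    fixation_report: str
    output_dir: str
    aoi_configs: dict[str, str] = field(default_factory=dict)  # picture_id -> path
    aoi_buffer_px: float = 0.0
    membership: str = "onset"  # fixation-window membership mode
    pause_threshold_ms: int = 2000
    conjunctive_suffix_limit: int = 2
    resegment: bool = False
    run_stats: bool = True
    type_key: str = "lemma"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.membership not in MEMBERSHIP_MODES:
            raise ValidationError(f"membership must be one of {MEMBERSHIP_MODES}")
        if self.type_key not in ("lemma", "surface"):
            raise ValidationError("type_key must be 'lemma' or 'surface'")

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        return cls(**doc)


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"stage {name!r}: {exc}")

    return wrap


def load_trials(config: RunConfig) -> list[TrialRecord]:
    """Stage 1-2: read transcripts and attach fixation streams."""
    fail = _stage("read")
    tdir = Path(config.transcripts_dir)
    paths = sorted(tdir.glob("*.yaml"))
    if not paths:
        raise fail(ValueError(f"no transcript YAMLs in {tdir}"))
    try:
        trials = [read_transcript(p) for p in paths]
        fixation_trials = read_fixation_report(config.fixation_report)
    except (OSError, Exception) as exc:
        if isinstance(exc, PipelineError):
            raise
        raise fail(exc)

    out = []
    for trial in trials:
        if trial.trial_label not in fixation_trials:
            raise fail(KeyError(f"no fixation data for trial {trial.trial_label!r}"))
        out.append(trial.with_fixations(fixation_trials[trial.trial_label]))
    return out


def load_regions(config: RunConfig) -> dict[str, list]:
    fail = _stage("aoi_config")
    regions = {}
    try:
        for picture in PICTURES:
            if picture in config.aoi_configs:
                regions[picture] = read_aoi_config(config.aoi_configs[picture])
            else:
                regions[picture] = packaged_aoi_config(picture)
    except Exception as exc:
        raise fail(exc)
    return regions


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of the artifacts."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    trials = load_trials(config)
    regions = load_regions(config)

    # validate AOI references
    for trial in trials:
        labels = {r.label for r in regions[trial.picture_id]}
        for utt in trial.utterances:
            if utt.aoi_label is not None and utt.aoi_label not in labels:
                raise PipelineError(
                    f"stage 'validate': trial {trial.trial_label}: utterance "
                    f"{utt.index} references unknown AOI {utt.aoi_label!r}"
                )

    if config.resegment:
        seg_config = SegmentationConfig(
            pause_threshold_ms=config.pause_threshold_ms,
            conjunctive_suffix_limit=config.conjunctive_suffix_limit,
        )
        diffs = []
        for trial in trials:
            resegmented = segment_utterances(trial.tokens(), seg_config)
            diff = boundary_diff(trial.utterances, resegmented)
            diff["trial"] = trial.trial_label
            diffs.append(diff)
        path = out_dir / "segmentation_diff.json"
        path.write_text(json.dumps(diffs, indent=2, sort_keys=True))
        artifacts["segmentation_diff"] = path

    rows: list[MetricsRow] = []
    audit: list[dict] = []
    for trial in trials:
        try:
            labelled = assign_fixations(
                trial.fixations, regions[trial.picture_id], config.aoi_buffer_px
            )
            scored = trial.with_fixations(labelled)
            result = prespeech_metrics(scored, membership=config.membership)
            rows.append(
                compute_metrics_row(
                    trial,
                    prespeech_count_per_utt=(
                        result.count_per_utt if result.count_per_utt is not None else float("nan")
                    ),
                    prespeech_dur_per_utt=(
                        result.dur_per_utt if result.dur_per_utt is not None else float("nan")
                    ),
                    type_key=config.type_key,
                )
            )
        except Exception as exc:
            raise PipelineError(f"stage 'metrics': trial {trial.trial_label}: {exc}")
        for idx, count, dur in zip(
            result.utterance_indices, result.counts, result.durations_ms
        ):
            audit.append(
                {
                    "trial": trial.trial_label,
                    "utterance": idx,
                    "prespeech_count": count,
                    "prespeech_dur_ms": dur,
                }
            )

    metrics_path = out_dir / "metrics.csv"
    write_metrics_csv(metrics_path, rows)
    artifacts["metrics"] = metrics_path
    audit_path = out_dir / "prespeech_audit.tsv"
    pd.DataFrame(audit).to_csv(audit_path, sep="\t", index=False)
    artifacts["audit"] = audit_path

    if config.run_stats:
        try:
            frame = pd.DataFrame([r.to_dict() for r in rows])
            tables = []
            report_lines = []
            for name, within, kind in ANOVA_SPECS:
                if kind is None:
                    table = mixed_anova(frame, dv=name, within=within)
                else:
                    table = mixed_anova(melt_pos(frame, kind), dv="value", within=within)
                    table = type(table)(dv=name, effects=table.effects)
                tables.append(table.to_frame())
                report_lines.append(table.report())
            for picture in PICTURES:
                sub = frame[frame.picture_id == picture]
                res = two_sample_t(
                    sub[sub.group == "younger"].wpm, sub[sub.group == "older"].wpm
                )
                report_lines.append(f"WPM t-test ({picture}): {res.format()}")
        except Exception as exc:
            raise PipelineError(f"stage 'stats': {exc}")
        anova_path = out_dir / "anova.csv"
        pd.concat(tables, ignore_index=True).to_csv(anova_path, index=False)
        artifacts["anova"] = anova_path
        report_path = out_dir / "report.txt"
        report_path.write_text("\n\n".join(report_lines) + "\n")
        artifacts["report"] = report_path

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_trials": len(trials),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return artifacts


def write_cohort_tree(sample, out_dir) -> dict[str, Path]:
    """Write a generated cohort as a full input tree.

    Produces ``transcripts/*.yaml``, ``fixations.tsv``, per-picture
    AOI configs, and a manifest of the configured ground truth; the
    tree feeds straight into :func:`run_pipeline`.
    """
    out_dir = Path(out_dir)
    tdir = out_dir / "transcripts"
    tdir.mkdir(parents=True, exist_ok=True)
    fixation_trials = {}
    for trial in sample:
        write_transcript(tdir / f"{trial.trial_label}.yaml", trial)
        fixation_trials[trial.trial_label] = trial.fixations
    fx_path = out_dir / "fixations.tsv"
    write_fixation_report(fx_path, fixation_trials)
    aoi_paths = {}
    for picture in PICTURES:
        path = out_dir / f"aoi_{picture}.yaml"
        write_aoi_config(path, packaged_aoi_config(picture))
        aoi_paths[picture] = path
    truth = {
        "config": asdict(sample.config),
        "warnings": sample.warnings,
        "expected_prespeech": {
            f"{g}/{p}": sample.config.expected_prespeech(g, p)
            for g in ("younger", "older")
            for p in PICTURES
        },
    }
    manifest_path = out_dir / "truth.json"
    manifest_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {
        "transcripts": tdir,
        "fixations": fx_path,
        "truth": manifest_path,
        **{f"aoi_{k}": v for k, v in aoi_paths.items()},
    }
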