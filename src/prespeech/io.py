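"""Readers and writers for the external formats.

Three on-disk formats are supported:

* **Fixation report** — tab-separated, one fixation per row, in the
  dialect of an EyeLink Data Viewer fixation report (configurable
  column names; defaults ``TRIAL_LABEL``, ``CURRENT_FIX_START``,
  ``CURRENT_FIX_END``, ``CURRENT_FIX_X``, ``CURRENT_FIX_Y``).
* **Transcript** — one YAML document per trial holding participant,
  group, picture, task duration, and the utterance/token structure
  with millisecond timing (utterance boundaries are measured upstream,
  e.g. in Praat; they are input, never computed here).
* **AOI config** — one YAML document per picture listing the twelve
  labelled polygons with their role (active agent vs static object).

Every reader fails loudly with the location of the offending record:
the metric denominators depend on completeness, so nothing is skipped.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from shapely.geometry import Polygon

from .errors import ConfigError, FormatError, GeometryError, ParseError, ValidationError
from .types import (
    METRICS_COLUMNS,
    AOIRegion,
    FixationEvent,
    MetricsRow,
    Token,
    TrialRecord,
    Utterance,
)

PathLike = Union[str, Path]

DEFAULT_FIXATION_COLUMNS = {
    "trial": "TRIAL_LABEL",
    "start": "CURRENT_FIX_START",
    "end": "CURRENT_FIX_END",
    "x": "CURRENT_FIX_X",
    "y": "CURRENT_FIX_Y",
}

_TOKEN_FIELDS = (
    "surface",
    "lemma",
    "pos",
    "intelligible",
    "ciu",
    "sentence_ending_particle",
    "conjunction",
    "conjunctive_suffix",
    "intonation_shift_after",
    "contextually_connected_to_next",
    "pause_after_ms",
    "onset_ms",
    "offset_ms",
)


# ---------------------------------------------------------------------------
# Fixation reports (TSV)
# ---------------------------------------------------------------------------

def read_fixation_report(
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> dict[str, list[FixationEvent]]:
    """Read a tab-separated fixation report, grouped by trial label.

    Events are returned sorted by onset within each trial; times are
    converted to integer milliseconds. Fixations whose coordinates lie
    outside the screen are flagged ``off_screen`` but kept.
    """
    columns = dict(DEFAULT_FIXATION_COLUMNS)
    if column_map:
        columns.update(column_map)

    trials: dict[str, list[FixationEvent]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        index = {}
        for key, name in columns.items():
            if name not in header:
                raise FormatError(f"{path}: missing column {name!r} (mapped to {key!r})")
            index[key] = header.index(name)

        for row_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            label = row[index["trial"]].strip()
            try:
                start = int(round(float(row[index["start"]])))
                end = int(round(float(row[index["end"]])))
                x = float(row[index["x"]])
                y = float(row[index["y"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: non-numeric cell at row {row_no}: {exc}")
            event = FixationEvent(onset_ms=start, offset_ms=end, x_px=x, y_px=y)
            event.off_screen = not event.on_screen()
            trials.setdefault(label, []).append(event)

    for events in trials.values():
        events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
    return trials


def write_fixation_report(
    path: PathLike,
    trials: Mapping[str, Sequence[FixationEvent]],
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write fixation events in the same TSV dialect the reader accepts."""
    columns = dict(DEFAULT_FIXATION_COLUMNS)
    if column_map:
        columns.update(column_map)
    order = ["trial", "start", "end", "x", "y"]
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([columns[k] for k in order])
        for label in trials:
            for ev in trials[label]:
                writer.writerow(
                    [label, ev.onset_ms, ev.offset_ms, repr(ev.x_px), repr(ev.y_px)]
                )


# ---------------------------------------------------------------------------
# Transcripts (YAML)
# ---------------------------------------------------------------------------

def _token_from_mapping(data: Mapping, where: str) -> Token:
    unknown = set(data) - set(_TOKEN_FIELDS)
    if unknown:
        raise FormatError(f"{where}: unknown token fields {sorted(unknown)}")
    for required in ("surface", "lemma", "pos"):
        if required not in data:
            raise FormatError(f"{where}: token missing field {required!r}")
    try:
        return Token(**data)
    except TypeError as exc:
        raise FormatError(f"{where}: {exc}")


def read_transcript(path: PathLike) -> TrialRecord:
    """Read one trial's transcript (utterances + tokens, no fixations).

    Enforces the token and utterance invariants: a CIU must be an
    intelligible word, utterance onset/offset must equal the first/last
    token times, and utterance intervals must not overlap.
    """
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: expected a mapping at the top level")
    for required in ("participant_id", "group", "picture_id", "task_duration_ms", "utterances"):
        if required not in doc:
            raise FormatError(f"{path}: missing field {required!r}")

    utterances: list[Utterance] = []
    for i, item in enumerate(doc["utterances"]):
        where = f"{path}: utterance {i}"
        if "tokens" not in item or not item["tokens"]:
            raise FormatError(f"{where}: missing or empty tokens")
        tokens = [
            _token_from_mapping(tok, f"{where}, token {j}")
            for j, tok in enumerate(item["tokens"])
        ]
        utt = Utterance(index=i, tokens=tokens, aoi_label=item.get("aoi_label"))
        if "onset_ms" in item and item["onset_ms"] != utt.onset_ms:
            raise ValidationError(
                f"{where}: onset_ms {item['onset_ms']} != first token onset {utt.onset_ms}"
            )
        if "offset_ms" in item and item["offset_ms"] != utt.offset_ms:
            raise ValidationError(
                f"{where}: offset_ms {item['offset_ms']} != last token offset {utt.offset_ms}"
            )
        utterances.append(utt)

    for prev, nxt in zip(utterances, utterances[1:]):
        if nxt.onset_ms < prev.offset_ms:
            raise ValidationError(
                f"{path}: utterances {prev.index} and {nxt.index} overlap "
                f"([{prev.onset_ms},{prev.offset_ms}] vs [{nxt.onset_ms},{nxt.offset_ms}])"
            )

    return TrialRecord(
        participant_id=str(doc["participant_id"]),
        group=doc["group"],
        picture_id=doc["picture_id"],
        task_duration_ms=int(doc["task_duration_ms"]),
        utterances=utterances,
    )


def write_transcript(path: PathLike, trial: TrialRecord) -> None:
    """Write a trial's transcript as YAML (fixations are not stored here)."""
    doc = {
        "participant_id": trial.participant_id,
        "group": trial.group,
        "picture_id": trial.picture_id,
        "task_duration_ms": trial.task_duration_ms,
        "utterances": [
            {
                "onset_ms": utt.onset_ms,
                "offset_ms": utt.offset_ms,
                **({"aoi_label": utt.aoi_label} if utt.aoi_label is not None else {}),
                "tokens": [
                    {name: getattr(tok, name) for name in _TOKEN_FIELDS}
                    for tok in utt.tokens
                ],
            }
            for utt in trial.utterances
        ],
    }
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


# ---------------------------------------------------------------------------
# AOI configurations (YAML)
# ---------------------------------------------------------------------------

def _validate_polygon(label: str, vertices: list[tuple[float, float]]) -> None:
    if len(vertices) < 3:
        raise GeometryError(f"AOI {label!r}: polygon needs >= 3 vertices")
    if len({tuple(v) for v in vertices}) < 3:
        raise GeometryError(f"AOI {label!r}: fewer than 3 distinct vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or not poly.is_simple or poly.area <= 0:
        raise GeometryError(f"AOI {label!r}: polygon is not simple/valid")


def read_aoi_config(path: PathLike) -> list[AOIRegion]:
    """Read one picture's AOI polygon configuration."""
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping) or "picture_id" not in doc or "regions" not in doc:
        raise FormatError(f"{path}: expected fields picture_id and regions")
    picture_id = doc["picture_id"]
    regions: list[AOIRegion] = []
    seen: set[str] = set()
    for item in doc["regions"]:
        for required in ("label", "role", "vertices"):
            if required not in item:
                raise FormatError(f"{path}: region missing field {required!r}")
        label = item["label"]
        if label in seen:
            raise ConfigError(f"{path}: duplicate AOI label {label!r}")
        seen.add(label)
        vertices = [(float(x), float(y)) for x, y in item["vertices"]]
        _validate_polygon(label, vertices)
        regions.append(
            AOIRegion(label=label, picture_id=picture_id, vertices=vertices, role=item["role"])
        )
    return regions


def write_aoi_config(path: PathLike, regions: Sequence[AOIRegion]) -> None:
    if not regions:
        raise ConfigError("cannot write an empty AOI configuration")
    picture_ids = {r.picture_id for r in regions}
    if len(picture_ids) != 1:
        raise ConfigError("an AOI config holds regions of exactly one picture")
    doc = {
        "picture_id": regions[0].picture_id,
        "regions": [
            {
                "label": r.label,
                "role": r.role,
                "vertices": [[float(x), float(y)] for x, y in r.vertices],
            }
            for r in regions
        ],
    }
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


def packaged_aoi_config(picture_id: str) -> list[AOIRegion]:
    """Load the packaged AOI configuration for one picture.

    The twelve labels and agent/object roles per picture follow the
    published AOI inventory; the vertex coordinates are synthetic
    stand-ins (the study's freehand polygons were never published) laid
    out on the 1680 x 1050 screen. See ``data/aoi_*_synthetic.yaml``.
    """
    name = f"aoi_{picture_id}_synthetic.yaml"
    resource = importlib.resources.files("prespeech.data").joinpath(name)
    with importlib.resources.as_file(resource) as path:
        return read_aoi_config(path)


# ---------------------------------------------------------------------------
# Metrics table (CSV)
# ---------------------------------------------------------------------------

def metrics_to_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([row.to_dict() for row in rows], columns=METRICS_COLUMNS)


def write_metrics_csv(path: PathLike, rows: Sequence[MetricsRow]) -> None:
    metrics_to_frame(rows).to_csv(path, index=False)


def read_metrics_csv(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing metrics columns {sorted(missing)}")
    return frame[METRICS_COLUMNS]
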