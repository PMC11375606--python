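"""Gaze-speech alignment: AOI hit-testing and pre-speech fixations.

A *pre-speech fixation* for utterance *i* is a fixation on the AOI
that utterance *i* describes, occurring in the planning window that
runs from the onset of utterance *i - 1* to the onset of utterance
*i* (language planning is incremental: the next utterance is prepared
while the current one is spoken). Only AOI-related utterances are
scored — commentary not tied to a picture element contributes neither
counts nor denominator. Per-utterance counts and summed durations are
aggregated and divided by the number of AOI-related utterances.

Window conventions:

* the first utterance's window starts at picture onset (t = 0);
* windows are half-open ``[start, end)`` — a fixation starting exactly
  at an utterance onset belongs to the next window;
* a fixation belongs to a window if its *onset* lies inside it, and by
  default its full duration is credited (fixations are atomic events
  in Data-Viewer-style reports); ``membership="truncate"`` instead
  clips the credited duration at the window end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import ValidationError
from .types import AOIRegion, FixationEvent, TrialRecord

MEMBERSHIP_MODES = ("onset", "truncate")


def _polygons(regions: Sequence[AOIRegion], buffer_px: float) -> list[Polygon]:
    polys = [Polygon(r.vertices) for r in regions]
    if buffer_px > 0:
        # uniform outward buffer emulating the study's slightly-enlarged
        # freehand AOIs; packaged synthetic polygons are pre-buffered
        polys = [p.buffer(buffer_px) for p in polys]
    return polys


def assign_fixations(
    fixations: Sequence[FixationEvent],
    regions: Sequence[AOIRegion],
    buffer_px: float = 0.0,
) -> list[FixationEvent]:
    """Label each fixation with the AOI containing its gaze position.

    Point-in-polygon with the boundary counted inside; when buffered
    polygons overlap, the first matching region in input order wins.
    Off-screen fixations stay unlabelled. Returns new events; the
    input is not mutated.
    """
    pictures = {r.picture_id for r in regions}
    if len(pictures) > 1:
        raise ValidationError(f"regions from several pictures: {sorted(pictures)}")
    polys = _polygons(regions, buffer_px)
    out: list[FixationEvent] = []
    for fx in fixations:
        label: Optional[str] = None
        if not fx.off_screen and fx.on_screen():
            point = Point(fx.x_px, fx.y_px)
            for region, poly in zip(regions, polys):
                if poly.covers(point):
                    label = region.label
                    break
        out.append(
            FixationEvent(
                onset_ms=fx.onset_ms,
                offset_ms=fx.offset_ms,
                x_px=fx.x_px,
                y_px=fx.y_px,
                aoi_label=label,
                off_screen=fx.off_screen or not fx.on_screen(),
            )
        )
    return out


@dataclass(frozen=True)
class PrespeechWindow:
    """The planning window preceding one utterance, half-open [start, end)."""

    utterance_index: int
    start_ms: int
    end_ms: int

    def contains_onset(self, t: int) -> bool:
        return self.start_ms <= t < self.end_ms


def prespeech_window(trial: TrialRecord, i: int) -> PrespeechWindow:
    """Planning window for utterance ``i``.

    ``[onset(u_{i-1}), onset(u_i))`` for ``i > 0``; the first
    utterance's window starts at picture onset, ``[0, onset(u_0))``.
    Consecutive windows tile ``[0, last onset)`` without overlap.
    """
    if not 0 <= i < len(trial.utterances):
        raise IndexError(f"utterance index {i} out of range (trial has {len(trial.utterances)})")
    start = 0 if i == 0 else trial.utterances[i - 1].onset_ms
    return PrespeechWindow(
        utterance_index=i, start_ms=start, end_ms=trial.utterances[i].onset_ms
    )


@dataclass(frozen=True)
class PrespeechResult:
    """Per-utterance pre-speech fixation tallies and their aggregates.

    ``utterance_indices`` lists the AOI-related utterances (the
    denominator population); ``counts`` and ``durations_ms`` align
    with it. Aggregates are ``None`` when no utterance is AOI-related
    (the statistic is undefined, not zero).
    """

    utterance_indices: tuple[int, ...]
    counts: tuple[int, ...]
    durations_ms: tuple[int, ...]

    @property
    def n_aoi_utterances(self) -> int:
        return len(self.utterance_indices)

    @property
    def count_per_utt(self) -> Optional[float]:
        if not self.utterance_indices:
            return None
        return float(np.sum(self.counts)) / self.n_aoi_utterances

    @property
    def dur_per_utt(self) -> Optional[float]:
        if not self.utterance_indices:
            return None
        return float(np.sum(self.durations_ms)) / self.n_aoi_utterances


def prespeech_metrics(
    trial: TrialRecord, membership: str = "onset"
) -> PrespeechResult:
    """Pre-speech fixation count and duration statistics for a trial.

    Requires AOI-labelled fixations (see :func:`assign_fixations`) and
    AOI-mapped utterances. For each AOI-related utterance, fixations
    whose onset falls in its planning window *and* whose AOI label
    matches the utterance's AOI are counted and their durations summed.
    """
    if membership not in MEMBERSHIP_MODES:
        raise ValidationError(
            f"membership must be one of {MEMBERSHIP_MODES}, got {membership!r}"
        )
    indices: list[int] = []
    counts: list[int] = []
    durations: list[int] = []
    for i, utt in enumerate(trial.utterances):
        if not utt.is_aoi_related:
            continue
        window = prespeech_window(trial, i)
        count = 0
        total = 0
        for fx in trial.fixations:
            if fx.aoi_label != utt.aoi_label:
                continue
            if not window.contains_onset(fx.onset_ms):
                continue
            count += 1
            if membership == "truncate":
                total += min(fx.offset_ms, window.end_ms) - fx.onset_ms
            else:
                total += fx.duration_ms
        indices.append(i)
        counts.append(count)
        durations.append(total)
    return PrespeechResult(
        utterance_indices=tuple(indices),
        counts=tuple(counts),
        durations_ms=tuple(durations),
    )
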