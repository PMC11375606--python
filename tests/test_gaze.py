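"""AOI hit-testing and pre-speech fixation statistics."""

import dataclasses

import numpy as np
import pytest

from prespeech.errors import ValidationError
from prespeech.gaze import (
    assign_fixations,
    prespeech_metrics,
    prespeech_window,
)
from prespeech.io import packaged_aoi_config
from prespeech.types import AOIRegion, FixationEvent, TrialRecord, Utterance

from conftest import make_utterance, random_labelled_trial


# ---------------------------------------------------------------------------
# independent geometry oracle: even-odd ray casting
# ---------------------------------------------------------------------------

def ray_cast_contains(x, y, vertices):
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def oracle_label(x, y, regions):
    for region in regions:
        if ray_cast_contains(x, y, region.vertices):
            return region.label
    return None


def fixation_at(x, y, onset=0, offset=100, label=None):
    return FixationEvent(onset_ms=onset, offset_ms=offset, x_px=x, y_px=y, aoi_label=label)


class TestAssignFixations:
    def test_centroid_gets_the_label(self):
        regions = packaged_aoi_config("beach")
        for region in regions:
            xs = [v[0] for v in region.vertices]
            ys = [v[1] for v in region.vertices]
            fx = fixation_at(sum(xs) / len(xs), sum(ys) / len(ys))
            [labelled] = assign_fixations([fx], regions)
            assert labelled.aoi_label == region.label

    def test_point_outside_all_polygons_unlabelled(self):
        regions = packaged_aoi_config("beach")
        [labelled] = assign_fixations([fixation_at(5.0, 5.0)], regions)
        assert labelled.aoi_label is None

    def test_off_screen_fixation_flagged_and_unlabelled(self):
        regions = packaged_aoi_config("beach")
        [labelled] = assign_fixations([fixation_at(-10.0, 200.0)], regions)
        assert labelled.off_screen and labelled.aoi_label is None

    def test_buffer_extends_the_region(self):
        regions = [
            AOIRegion(
                label="sq", picture_id="beach",
                vertices=[(100, 100), (200, 100), (200, 200), (100, 200)],
                role="static_object",
            )
        ]
        fx = fixation_at(210.0, 150.0)
        assert assign_fixations([fx], regions)[0].aoi_label is None
        assert assign_fixations([fx], regions, buffer_px=15)[0].aoi_label == "sq"

    def test_mixed_picture_regions_rejected(self):
        regions = packaged_aoi_config("beach") + packaged_aoi_config("han_river")
        with pytest.raises(ValidationError):
            assign_fixations([fixation_at(10, 10)], regions)

    def test_random_points_match_ray_casting_oracle(self, rng):
        regions = packaged_aoi_config("han_river")
        fixations = [
            fixation_at(float(rng.uniform(0, 1680)), float(rng.uniform(0, 1050)))
            for _ in range(3000)
        ]
        labelled = assign_fixations(fixations, regions)
        for fx in labelled:
            assert fx.aoi_label == oracle_label(fx.x_px, fx.y_px, regions)


class TestPrespeechWindow:
    def three_utterance_trial(self):
        utts = [
            make_utterance(0, 1000, 2000, aoi_label="a"),
            make_utterance(1, 4000, 3000, aoi_label="b"),
            make_utterance(2, 9000, 1000, aoi_label="a"),
        ]
        return TrialRecord(
            participant_id="p", group="younger", picture_id="beach",
            task_duration_ms=12000, utterances=utts,
        )

    def test_interior_window_spans_previous_onset_to_current(self):
        w = prespeech_window(self.three_utterance_trial(), 1)
        assert (w.start_ms, w.end_ms) == (1000, 4000)

    def test_first_window_starts_at_picture_onset(self):
        w = prespeech_window(self.three_utterance_trial(), 0)
        assert (w.start_ms, w.end_ms) == (0, 1000)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            prespeech_window(self.three_utterance_trial(), 3)

    def test_windows_tile_zero_to_last_onset(self, rng):
        for _ in range(50):
            trial = random_labelled_trial(rng)
            windows = [prespeech_window(trial, i) for i in range(len(trial.utterances))]
            assert windows[0].start_ms == 0
            for prev, nxt in zip(windows, windows[1:]):
                assert prev.end_ms == nxt.start_ms
            assert windows[-1].end_ms == trial.utterances[-1].onset_ms

    def test_half_open_boundary_onset_belongs_to_next_window(self):
        trial = self.three_utterance_trial()
        w0, w1 = prespeech_window(trial, 0), prespeech_window(trial, 1)
        assert not w0.contains_onset(1000) and w1.contains_onset(1000)


def prespeech_oracle(trial):
    """Quadratic brute force over (utterance, fixation) pairs."""
    onsets = [u.onset_ms for u in trial.utterances]
    per_utt = {}
    for i, utt in enumerate(trial.utterances):
        if utt.aoi_label is None:
            continue
        start = 0 if i == 0 else onsets[i - 1]
        end = onsets[i]
        count, dur = 0, 0
        for fx in trial.fixations:
            if fx.aoi_label == utt.aoi_label and start <= fx.onset_ms < end:
                count += 1
                dur += fx.offset_ms - fx.onset_ms
        per_utt[i] = (count, dur)
    return per_utt


class TestPrespeechMetrics:
    def hand_trial(self):
        utt = make_utterance(0, 2000, 1000, aoi_label="dog")
        fixations = [
            fixation_at(0, 0, onset=500, offset=900, label="dog"),
            fixation_at(0, 0, onset=1000, offset=1100, label="cat"),
            fixation_at(0, 0, onset=1200, offset=1800, label="dog"),
        ]
        return TrialRecord(
            participant_id="p", group="younger", picture_id="beach",
            task_duration_ms=4000, utterances=[utt], fixations=fixations,
        )

    def test_hand_checkable_counts_and_durations(self):
        result = prespeech_metrics(self.hand_trial())
        assert result.counts == (2,)
        assert result.durations_ms == (1000,)
        assert result.count_per_utt == 2.0
        assert result.dur_per_utt == 1000.0

    def test_trial_without_aoi_related_utterances_has_missing_aggregates(self):
        utt = make_utterance(0, 2000, 1000)  # personal commentary, no AOI
        trial = TrialRecord(
            participant_id="p", group="younger", picture_id="beach",
            task_duration_ms=4000, utterances=[utt],
            fixations=[fixation_at(0, 0, onset=500, offset=900, label="dog")],
        )
        result = prespeech_metrics(trial)
        assert result.n_aoi_utterances == 0
        assert result.count_per_utt is None and result.dur_per_utt is None

    def test_random_trials_match_quadratic_oracle(self, rng):
        for _ in range(150):
            trial = random_labelled_trial(rng)
            result = prespeech_metrics(trial)
            expected = prespeech_oracle(trial)
            assert list(result.utterance_indices) == sorted(expected)
            for i, count, dur in zip(
                result.utterance_indices, result.counts, result.durations_ms
            ):
                assert (count, dur) == expected[i]

    def test_translation_invariance(self, rng):
        trial = random_labelled_trial(rng, n_utterances=5, n_fixations=20)
        shift = 5000

        def shift_token(tok):
            return dataclasses.replace(
                tok, onset_ms=tok.onset_ms + shift, offset_ms=tok.offset_ms + shift
            )

        shifted = TrialRecord(
            participant_id="p", group="younger", picture_id="beach",
            task_duration_ms=trial.task_duration_ms + shift,
            utterances=[
                Utterance(index=u.index, tokens=[shift_token(t) for t in u.tokens],
                          aoi_label=u.aoi_label)
                for u in trial.utterances
            ],
            fixations=[
                dataclasses.replace(
                    f, onset_ms=f.onset_ms + shift, offset_ms=f.offset_ms + shift
                )
                for f in trial.fixations
            ],
        )
        a, b = prespeech_metrics(trial), prespeech_metrics(shifted)
        # the first window grows by the shift; fixations shift with it, so
        # per-utterance tallies beyond the first are unchanged and the first
        # utterance's tally is preserved because its fixations moved too
        assert a.counts == b.counts and a.durations_ms == b.durations_ms

    def test_removing_non_matching_fixations_changes_nothing(self, rng):
        for _ in range(20):
            trial = random_labelled_trial(rng, n_utterances=4, n_fixations=25)
            kept = []
            for fx in trial.fixations:
                matches = any(
                    utt.aoi_label == fx.aoi_label
                    and prespeech_window(trial, i).contains_onset(fx.onset_ms)
                    for i, utt in enumerate(trial.utterances)
                    if utt.aoi_label is not None
                )
                if matches:
                    kept.append(fx)
            pruned = trial.with_fixations(kept)
            a, b = prespeech_metrics(trial), prespeech_metrics(pruned)
            assert a.counts == b.counts and a.durations_ms == b.durations_ms

    def test_duration_bounded_below_by_count_times_min_duration(self, rng):
        for _ in range(30):
            trial = random_labelled_trial(rng)
            if not trial.fixations:
                continue
            min_dur = min(f.duration_ms for f in trial.fixations)
            result = prespeech_metrics(trial)
            for count, dur in zip(result.counts, result.durations_ms):
                assert dur >= count * min_dur

    def test_truncate_membership_clips_at_window_end(self):
        utt0 = make_utterance(0, 2000, 500, aoi_label="dog")
        utt1 = make_utterance(1, 4000, 500, aoi_label="dog")
        fx = fixation_at(0, 0, onset=3500, offset=6000, label="dog")  # straddles 4000
        trial = TrialRecord(
            participant_id="p", group="younger", picture_id="beach",
            task_duration_ms=8000, utterances=[utt0, utt1], fixations=[fx],
        )
        full = prespeech_metrics(trial, membership="onset")
        clipped = prespeech_metrics(trial, membership="truncate")
        assert full.durations_ms == (0, 2500)
        assert clipped.durations_ms == (0, 500)
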