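"""Pre-speech fixations: AOI hit-testing and window scoring.

Loads the packaged (synthetic-coordinate) Beach AOI polygons, builds a
trial with two AOI-related utterances and a handful of fixations, and
scores the pre-speech statistic: fixations on the upcoming utterance's
AOI whose onset falls between the previous utterance's onset and the
current one's.
"""

from prespeech import FixationEvent, Token, TrialRecord, Utterance
from prespeech.gaze import assign_fixations, prespeech_metrics, prespeech_window
from prespeech.io import packaged_aoi_config

regions = packaged_aoi_config("beach")
by_label = {r.label: r for r in regions}


def centroid(label):
    vs = by_label[label].vertices
    return sum(v[0] for v in vs) / len(vs), sum(v[1] for v in vs) / len(vs)


def utterance(i, label, onset):
    tokens = [Token(surface=f"w{i}", lemma=f"w{i}", pos="common_noun",
                    onset_ms=onset, offset_ms=onset + 1500)]
    return Utterance(index=i, tokens=tokens, aoi_label=label)


dog_xy = centroid("barking_dog")
sea_xy = centroid("sea")
fixations = [
    FixationEvent(onset_ms=800, offset_ms=1300, x_px=dog_xy[0], y_px=dog_xy[1]),
    FixationEvent(onset_ms=1500, offset_ms=1900, x_px=dog_xy[0], y_px=dog_xy[1]),
    FixationEvent(onset_ms=2500, offset_ms=3600, x_px=sea_xy[0], y_px=sea_xy[1]),
    FixationEvent(onset_ms=4000, offset_ms=4200, x_px=5.0, y_px=5.0),  # no AOI
]

trial = TrialRecord(
    participant_id="demo", group="older", picture_id="beach", task_duration_ms=10_000,
    utterances=[utterance(0, "barking_dog", 2000), utterance(1, "sea", 5000)],
    fixations=[],
)
labelled = assign_fixations(fixations, regions)
trial = trial.with_fixations(labelled)

result = prespeech_metrics(trial)
for i, count, dur in zip(result.utterance_indices, result.counts, result.durations_ms):
    window = prespeech_window(trial, i)
    label = trial.utterances[i].aoi_label
    print(f"utterance {i} ({label}): window [{window.start_ms}, {window.end_ms}) ms "
          f"-> {count} pre-speech fixations, {dur} ms")
print(f"aggregates: {result.count_per_utt:.1f} fixations/utterance, "
      f"{result.dur_per_utt:.1f} ms/utterance")
print()
print("Both dog fixations precede the dog utterance inside its window; the sea")
print("fixation precedes the sea utterance; the unassigned fixation never counts.")
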