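"""Shared fixtures and random-input builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from prespeech.types import FixationEvent, Token, TrialRecord, Utterance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_token(
    surface="tok",
    lemma=None,
    pos="common_noun",
    onset_ms=0,
    offset_ms=0,
    **kwargs,
):
    return Token(
        surface=surface,
        lemma=lemma if lemma is not None else surface,
        pos=pos,
        onset_ms=onset_ms,
        offset_ms=max(offset_ms, onset_ms),
        **kwargs,
    )


def random_annotated_stream(rng, n_tokens=None):
    """A random marker/pause token stream for segmentation tests.

    Pauses mix zeros, values around the 2000 ms threshold (including
    exactly 2000), and clearly long pauses so every rule path is hit.
    """
    if n_tokens is None:
        n_tokens = int(rng.integers(1, 30))
    tokens = []
    clock = 0
    for i in range(n_tokens):
        duration = int(rng.integers(100, 600))
        u = rng.random()
        if u < 0.5:
            pause = 0
        elif u < 0.65:
            pause = 2000  # boundary: must not split
        else:
            pause = int(rng.integers(1, 4500))
        tokens.append(
            make_token(
                surface=f"t{i}",
                onset_ms=clock,
                offset_ms=clock + duration,
                sentence_ending_particle=bool(rng.random() < 0.15),
                conjunction=bool(rng.random() < 0.10),
                conjunctive_suffix=bool(rng.random() < 0.20),
                intonation_shift_after=bool(rng.random() < 0.10),
                contextually_connected_to_next=bool(rng.random() < 0.30),
                pause_after_ms=pause,
            )
        )
        clock += duration + pause
    return tokens


def make_utterance(index, onset_ms, duration_ms=500, n_tokens=2, aoi_label=None, **token_kwargs):
    slot = max(duration_ms // n_tokens, 1)
    tokens = [
        make_token(
            surface=f"u{index}t{j}",
            onset_ms=onset_ms + j * slot,
            offset_ms=onset_ms + duration_ms if j == n_tokens - 1 else onset_ms + (j + 1) * slot,
            **token_kwargs,
        )
        for j in range(n_tokens)
    ]
    return Utterance(index=index, tokens=tokens, aoi_label=aoi_label)


def random_labelled_trial(rng, labels=("a", "b", "c"), n_utterances=None, n_fixations=None):
    """A random trial with AOI-labelled utterances and fixations.

    Fixation AOI labels are set directly (geometry-free) so pre-speech
    scoring can be exercised against a brute-force oracle.
    """
    if n_utterances is None:
        n_utterances = int(rng.integers(1, 8))
    if n_fixations is None:
        n_fixations = int(rng.integers(0, 30))
    utterances = []
    clock = int(rng.integers(200, 2000))
    for i in range(n_utterances):
        duration = int(rng.integers(300, 2500))
        label = str(rng.choice(labels)) if rng.random() < 0.7 else None
        utterances.append(make_utterance(i, clock, duration, aoi_label=label))
        clock += duration + int(rng.integers(1, 1500))
    task_duration = clock + 500
    fixations = []
    for _ in range(n_fixations):
        onset = int(rng.integers(0, task_duration - 100))
        fixations.append(
            FixationEvent(
                onset_ms=onset,
                offset_ms=onset + int(rng.integers(50, 600)),
                x_px=float(rng.uniform(0, 1680)),
                y_px=float(rng.uniform(0, 1050)),
                aoi_label=str(rng.choice(labels)) if rng.random() < 0.8 else None,
            )
        )
    fixations = [f for f in fixations if f.offset_ms <= task_duration]
    fixations.sort(key=lambda f: f.onset_ms)
    return TrialRecord(
        participant_id="p1",
        group="younger",
        picture_id="beach",
        task_duration_ms=task_duration,
        utterances=utterances,
        fixations=fixations,
    )
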