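"""Informativeness and productivity measures for one trial.

Word and CIU counting follows the Nicholas & Brookshire convention:
the word count collects tokens that are intelligible in context (they
need not be accurate or relevant); CIUs are the subset of those words
that are additionally accurate, relevant and informative about the
picture. Both flags arrive as coder annotations. Rates are normalised
by the task duration in minutes.

Noun/verb productivity: nouns comprise common nouns, proper nouns and
pronouns; verbs comprise main and auxiliary verbs (serial verb
constructions make auxiliaries semantically contentful in Korean).
Tokens are occurrences, types are distinct lemmas within the trial
(lemma-based by default; surface-based counting is available because
inflection would otherwise inflate type counts). Counts are
normalised by the number of utterances in the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .types import MetricsRow, TrialRecord

MS_PER_MINUTE = 60_000.0


@dataclass(frozen=True)
class NVCounts:
    """Noun/verb token and type tallies, raw and per utterance."""

    nouns_token: int
    nouns_type: int
    verbs_token: int
    verbs_type: int
    n_utterances: int

    def __post_init__(self) -> None:
        if self.nouns_type > self.nouns_token or self.verbs_type > self.verbs_token:
            raise ValidationError("type count cannot exceed token count")
        if self.n_utterances == 0 and (self.nouns_token or self.verbs_token):
            raise ValidationError("nonzero counts with zero utterances")

    def _per_utt(self, value: int) -> float:
        return value / self.n_utterances if self.n_utterances else 0.0

    @property
    def nouns_token_per_utt(self) -> float:
        return self._per_utt(self.nouns_token)

    @property
    def nouns_type_per_utt(self) -> float:
        return self._per_utt(self.nouns_type)

    @property
    def verbs_token_per_utt(self) -> float:
        return self._per_utt(self.verbs_token)

    @property
    def verbs_type_per_utt(self) -> float:
        return self._per_utt(self.verbs_type)


def lexical_counts(trial: TrialRecord) -> tuple[int, int]:
    """Return (word_count, ciu_count) for a trial.

    Words are intelligible tokens; CIUs are the flagged subset (the
    ciu => intelligible invariant is enforced at token construction).
    """
    words = 0
    cius = 0
    for tok in trial.tokens():
        if tok.intelligible:
            words += 1
            if tok.ciu:
                cius += 1
    return words, cius


def _rate_per_minute(count: int, duration_ms: int) -> float:
    if duration_ms <= 0:
        raise ValidationError("task duration must be positive for rate measures")
    return count * MS_PER_MINUTE / duration_ms


def cius_per_minute(trial: TrialRecord) -> float:
    """CIU count normalised by task duration in minutes."""
    return _rate_per_minute(lexical_counts(trial)[1], trial.task_duration_ms)


def words_per_minute(trial: TrialRecord) -> float:
    """Word count (intelligible tokens) per minute of task time."""
    return _rate_per_minute(lexical_counts(trial)[0], trial.task_duration_ms)


def nv_counts(trial: TrialRecord, by: str = "lemma") -> NVCounts:
    """Noun/verb token and type tallies over the trial's intelligible tokens.

    ``by`` selects the identity key for type counting: ``"lemma"``
    (default) or ``"surface"``.
    """
    if by not in ("lemma", "surface"):
        raise ValidationError(f"type counting key must be 'lemma' or 'surface', got {by!r}")
    noun_tokens = 0
    verb_tokens = 0
    noun_ids: set[str] = set()
    verb_ids: set[str] = set()
    for tok in trial.tokens():
        if not tok.intelligible:
            continue
        key = tok.lemma if by == "lemma" else tok.surface
        if tok.is_noun:
            noun_tokens += 1
            noun_ids.add(key)
        elif tok.is_verb:
            verb_tokens += 1
            verb_ids.add(key)
    return NVCounts(
        nouns_token=noun_tokens,
        nouns_type=len(noun_ids),
        verbs_token=verb_tokens,
        verbs_type=len(verb_ids),
        n_utterances=len(trial.utterances),
    )


def compute_metrics_row(
    trial: TrialRecord,
    prespeech_count_per_utt: float = math.nan,
    prespeech_dur_per_utt: float = math.nan,
    type_key: str = "lemma",
) -> MetricsRow:
    """Assemble the full per-trial dependent-measure row.

    The pre-speech aggregates are supplied by the gaze module (NaN when
    no fixation data or no AOI-related utterance is available).
    """
    nv = nv_counts(trial, by=type_key)
    return MetricsRow(
        participant_id=trial.participant_id,
        group=trial.group,
        picture_id=trial.picture_id,
        cius_per_min=cius_per_minute(trial),
        nouns_token_per_utt=nv.nouns_token_per_utt,
        nouns_type_per_utt=nv.nouns_type_per_utt,
        verbs_token_per_utt=nv.verbs_token_per_utt,
        verbs_type_per_utt=nv.verbs_type_per_utt,
        prespeech_count_per_utt=prespeech_count_per_utt,
        prespeech_dur_per_utt=prespeech_dur_per_utt,
        wpm=words_per_minute(trial),
    )
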