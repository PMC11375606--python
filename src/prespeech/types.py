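"""Domain types for connected-speech + eye-tracking trials.

All times are integer milliseconds on a per-trial clock that starts at
picture onset (t = 0); a 1,000 Hz tracker makes milliseconds exact.
Pixel coordinates use the screen convention: origin at the top-left,
x rightward, y downward, on a 1680 x 1050 display.

Token-level annotations (part of speech, intelligibility, CIU status,
utterance-boundary markers) are *inputs* produced by human coders or by
the synthetic cohort generator; the pipeline never infers them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import ValidationError

SCREEN_WIDTH_PX = 1680
SCREEN_HEIGHT_PX = 1050

GROUPS = ("younger", "older")
PICTURES = ("han_river", "beach")

NOUN_POS = frozenset({"common_noun", "proper_noun", "pronoun"})
VERB_POS = frozenset({"main_verb", "aux_verb"})
POS_TAGS = NOUN_POS | VERB_POS | {"other"}

AOI_ROLES = ("active_agent", "static_object")


@dataclass
class Token:
    """One transcribed word with coder annotations.

    A CIU (correct information unit) must first be a countable word —
    intelligible in context — so ``ciu`` implies ``intelligible``.
    ``pause_after_ms`` is the silent gap to the next token (0 for the
    last token of a trial); ``None`` means the timing is unknown, which
    is only an error if a timing-dependent segmentation rule needs it.
    """

    surface: str
    lemma: str
    pos: str
    intelligible: bool = True
    ciu: bool = False
    sentence_ending_particle: bool = False
    conjunction: bool = False
    conjunctive_suffix: bool = False
    intonation_shift_after: bool = False
    contextually_connected_to_next: bool = False
    pause_after_ms: Optional[int] = 0
    onset_ms: int = 0
    offset_ms: int = 0

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise ValidationError(f"unknown pos tag {self.pos!r} on token {self.surface!r}")
        if self.ciu and not self.intelligible:
            raise ValidationError(
                f"token {self.surface!r}: ciu=True requires intelligible=True "
                "(a CIU is drawn from the initially counted intelligible words)"
            )
        if self.offset_ms < self.onset_ms:
            raise ValidationError(
                f"token {self.surface!r}: offset_ms {self.offset_ms} < onset_ms {self.onset_ms}"
            )
        if self.pause_after_ms is not None and self.pause_after_ms < 0:
            raise ValidationError(f"token {self.surface!r}: negative pause_after_ms")

    @property
    def is_noun(self) -> bool:
        return self.pos in NOUN_POS

    @property
    def is_verb(self) -> bool:
        return self.pos in VERB_POS


@dataclass
class Utterance:
    """A timed, contiguous token span, optionally mapped to one AOI.

    Utterance timing is carried by its tokens: onset is the first
    token's onset, offset the last token's offset.
    """

    index: int
    tokens: list[Token]
    aoi_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError(f"utterance {self.index}: empty token sequence")
        if self.index < 0:
            raise ValidationError("utterance index must be >= 0")

    @property
    def onset_ms(self) -> int:
        return self.tokens[0].onset_ms

    @property
    def offset_ms(self) -> int:
        return self.tokens[-1].offset_ms

    @property
    def is_aoi_related(self) -> bool:
        return self.aoi_label is not None


@dataclass
class FixationEvent:
    """One fixation: onset/offset on the trial clock, gaze position in px.

    ``off_screen`` flags events whose coordinates fall outside the
    display; they are kept (never silently dropped) but are excluded
    from AOI assignment.
    """

    onset_ms: int
    offset_ms: int
    x_px: float
    y_px: float
    aoi_label: Optional[str] = None
    off_screen: bool = False

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValidationError(
                f"fixation at {self.onset_ms} ms: offset must exceed onset"
            )

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms

    def on_screen(self) -> bool:
        return (
            0 <= self.x_px <= SCREEN_WIDTH_PX and 0 <= self.y_px <= SCREEN_HEIGHT_PX
        )


@dataclass
class AOIRegion:
    """A polygonal area of interest on one picture.

    ``role`` distinguishes depicted people/animals (``active_agent``)
    from background elements (``static_object``). The polygon must be
    simple (non-self-intersecting) with at least three vertices; this
    is validated with shapely at load time (see io.read_aoi_config).
    """

    label: str
    picture_id: str
    vertices: list[tuple[float, float]]
    role: str

    def __post_init__(self) -> None:
        if self.picture_id not in PICTURES:
            raise ValidationError(f"unknown picture_id {self.picture_id!r}")
        if self.role not in AOI_ROLES:
            raise ValidationError(f"unknown AOI role {self.role!r} for {self.label!r}")
        if len(self.vertices) < 3:
            raise ValidationError(f"AOI {self.label!r}: needs >= 3 vertices")


@dataclass
class TrialRecord:
    """One participant x picture session.

    Holds the utterance sequence (with tokens) and the fixation stream;
    ``task_duration_ms`` is the full description time for the picture,
    used to normalise the per-minute rates.
    """

    participant_id: str
    group: str
    picture_id: str
    task_duration_ms: int
    utterances: list[Utterance] = field(default_factory=list)
    fixations: list[FixationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.picture_id not in PICTURES:
            raise ValidationError(f"unknown picture_id {self.picture_id!r}")
        if self.task_duration_ms <= 0:
            raise ValidationError("task_duration_ms must be positive")
        prev_onset = None
        for utt in self.utterances:
            if not (0 <= utt.onset_ms and utt.offset_ms <= self.task_duration_ms):
                raise ValidationError(
                    f"trial {self.participant_id}/{self.picture_id}: utterance "
                    f"{utt.index} at [{utt.onset_ms}, {utt.offset_ms}] outside "
                    f"[0, {self.task_duration_ms}]"
                )
            if prev_onset is not None and utt.onset_ms <= prev_onset:
                raise ValidationError(
                    f"trial {self.participant_id}/{self.picture_id}: utterance "
                    f"onsets must be strictly increasing (utterance {utt.index})"
                )
            prev_onset = utt.onset_ms
        for fx in self.fixations:
            if not (0 <= fx.onset_ms and fx.offset_ms <= self.task_duration_ms):
                raise ValidationError(
                    f"trial {self.participant_id}/{self.picture_id}: fixation at "
                    f"[{fx.onset_ms}, {fx.offset_ms}] outside [0, {self.task_duration_ms}]"
                )

    @property
    def trial_label(self) -> str:
        return f"{self.participant_id}__{self.picture_id}"

    def tokens(self) -> list[Token]:
        return [tok for utt in self.utterances for tok in utt.tokens]

    def with_fixations(self, fixations: Sequence[FixationEvent]) -> "TrialRecord":
        return replace(self, fixations=list(fixations))


METRICS_COLUMNS = [
    "participant_id",
    "group",
    "picture_id",
    "cius_per_min",
    "nouns_token_per_utt",
    "nouns_type_per_utt",
    "verbs_token_per_utt",
    "verbs_type_per_utt",
    "prespeech_count_per_utt",
    "prespeech_dur_per_utt",
    "wpm",
]


@dataclass
class MetricsRow:
    """Per-trial dependent measures, one row of the metrics table.

    The pre-speech aggregates are NaN when a trial has no AOI-related
    utterance (the statistic is then undefined, not zero).
    """

    participant_id: str
    group: str
    picture_id: str
    cius_per_min: float
    nouns_token_per_utt: float
    nouns_type_per_utt: float
    verbs_token_per_utt: float
    verbs_type_per_utt: float
    prespeech_count_per_utt: float
    prespeech_dur_per_utt: float
    wpm: float

    def __post_init__(self) -> None:
        for name in METRICS_COLUMNS[3:]:
            value = getattr(self, name)
            if not math.isnan(value) and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.nouns_type_per_utt > self.nouns_token_per_utt + 1e-12:
            raise ValidationError("noun types cannot exceed noun tokens")
        if self.verbs_type_per_utt > self.verbs_token_per_utt + 1e-12:
            raise ValidationError("verb types cannot exceed verb tokens")

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRICS_COLUMNS}
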