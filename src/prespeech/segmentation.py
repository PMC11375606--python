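"""Utterance segmentation for annotated Korean connected speech.

An utterance is a sentence or a shorter unit. The segmentation rules,
applied to a coder-annotated token stream, are:

* **R1 — sentence-ending particle.** Break after a token flagged as a
  sentence-ending particle (e.g. *-ta*), unless it is contextually
  connected to the following words (a coder judgment carried on the
  token as ``contextually_connected_to_next``).
* **R2 — conjunction.** A conjunction (e.g. "and") opens a new
  utterance that runs to the next sentence-ending particle; the engine
  therefore breaks immediately *before* a conjunction token.
* **R3 — pause.** Break whenever the silent gap after a token exceeds
  the pause threshold (default 2000 ms; a gap of exactly 2000 ms does
  not split — the rule requires *more than* 2 seconds).
* **R4 — conjunctive suffix.** When speech continues through a
  conjunctive suffix (e.g. *-ko*), break at the first subsequent
  significant intonation shift or over-threshold pause; absent both,
  the utterance extends to the second conjunctive suffix and breaks
  there. The suffix counter resets at every utterance boundary.

When several rules fire at the same junction the break is the same
junction, so precedence only matters conceptually: the unconditional
pause rule dominates, then the sentence-ending rule (which carries the
continuation exception), then the conjunctive-suffix rules.

Intonation shifts and "contextually connected" are input flags set by
coders; no acoustic or semantic analysis happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .errors import AnnotationError, ValidationError
from .types import Token, Utterance

DEFAULT_PAUSE_THRESHOLD_MS = 2000
DEFAULT_CONJUNCTIVE_SUFFIX_LIMIT = 2


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds for the utterance segmentation rules.

    ``pause_threshold_ms``: silent gap above which R3 forces a break
    (strictly greater-than). ``conjunctive_suffix_limit``: the ordinal
    conjunctive suffix at which R4 breaks absent an intonation shift
    or pause (the convention is the second suffix).
    """

    pause_threshold_ms: int = DEFAULT_PAUSE_THRESHOLD_MS
    conjunctive_suffix_limit: int = DEFAULT_CONJUNCTIVE_SUFFIX_LIMIT

    def __post_init__(self) -> None:
        if self.pause_threshold_ms <= 0:
            raise ValidationError("pause_threshold_ms must be > 0")
        if self.conjunctive_suffix_limit < 1:
            raise ValidationError("conjunctive_suffix_limit must be >= 1")


def _break_junctions(
    tokens: Sequence[Token], config: SegmentationConfig
) -> Iterator[int]:
    """Yield indices i such that an utterance boundary falls after tokens[i].

    The final junction (after the last token) is implicit and not yielded.
    """
    suffixes_in_utterance = 0
    for i, tok in enumerate(tokens[:-1]):
        if tok.conjunctive_suffix:
            suffixes_in_utterance += 1
        nxt = tokens[i + 1]

        if tok.pause_after_ms is None:
            raise AnnotationError(
                f"token {i} ({tok.surface!r}): pause_after_ms unknown but the "
                "pause rule must be evaluated at this junction"
            )
        pause_break = tok.pause_after_ms > config.pause_threshold_ms  # R3
        sentence_break = (
            tok.sentence_ending_particle and not tok.contextually_connected_to_next
        )  # R1
        conjunction_break = nxt.conjunction  # R2: conjunction opens a new utterance
        intonation_break = (
            suffixes_in_utterance >= 1 and tok.intonation_shift_after
        )  # R4, intonation arm
        second_suffix_break = (
            tok.conjunctive_suffix
            and suffixes_in_utterance >= config.conjunctive_suffix_limit
        )  # R4, second-suffix arm

        if (
            pause_break
            or sentence_break
            or conjunction_break
            or intonation_break
            or second_suffix_break
        ):
            suffixes_in_utterance = 0
            yield i


def segment_utterances(
    tokens: Sequence[Token],
    config: SegmentationConfig | None = None,
) -> list[Utterance]:
    """Segment an annotated token stream into utterances (rules R1-R4).

    The concatenation of the output utterances' tokens reproduces the
    input exactly; an empty stream yields an empty result.
    """
    if config is None:
        config = SegmentationConfig()
    tokens = list(tokens)
    if not tokens:
        return []

    boundaries = list(_break_junctions(tokens, config))
    utterances: list[Utterance] = []
    start = 0
    for index, junction in enumerate(boundaries + [len(tokens) - 1]):
        utterances.append(Utterance(index=index, tokens=tokens[start : junction + 1]))
        start = junction + 1
    return utterances


def boundary_diff(
    reference: Sequence[Utterance], resegmented: Sequence[Utterance]
) -> dict:
    """Compare two segmentations of the same token stream.

    Boundaries are identified by the cumulative token count at each
    utterance end. Returns the boundary sets only present in one side,
    for audit output of the ``segment`` pipeline stage.
    """

    def ends(utts: Sequence[Utterance]) -> set[int]:
        total, out = 0, set()
        for utt in utts:
            total += len(utt.tokens)
            out.add(total)
        return out

    ref, new = ends(reference), ends(resegmented)
    return {
        "n_reference": len(reference),
        "n_resegmented": len(resegmented),
        "only_in_reference": sorted(ref - new),
        "only_in_resegmented": sorted(new - ref),
        "identical": ref == new,
    }
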