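"""Segment an annotated token stream into utterances.

Builds a small Korean-style token stream (romanised placeholders) with
coder annotations and applies the four segmentation rules: break after
a sentence-ending particle (unless contextually connected), before a
conjunction, after a pause of more than 2 s, and at the second
conjunctive suffix absent an intonation shift or long pause.
"""

from prespeech import Token, segment_utterances


def tok(surface, onset, **kw):
    return Token(surface=surface, lemma=surface, pos=kw.pop("pos", "other"),
                 onset_ms=onset, offset_ms=onset + 300, **kw)


tokens = [
    tok("ai-ka", 0, pos="common_noun"),
    tok("kong-ul", 400, pos="common_noun"),
    tok("cha-yo", 800, pos="main_verb", sentence_ending_particle=True),
    tok("kuliko", 1200, conjunction=True),          # conjunction opens a new utterance
    tok("kangaci-ka", 1600, pos="common_noun"),
    tok("cic-ko", 2000, pos="main_verb", conjunctive_suffix=True),
    tok("tali-ko", 2400, pos="main_verb", conjunctive_suffix=True),  # second suffix
    tok("salamtul-i", 2800, pos="common_noun", pause_after_ms=2500),  # > 2 s pause
    tok("manh-ayo", 5600, pos="main_verb", sentence_ending_particle=True),
]

for utt in segment_utterances(tokens):
    words = " ".join(t.surface for t in utt.tokens)
    print(f"utterance {utt.index}: [{utt.onset_ms:>4}-{utt.offset_ms:>4} ms] {words}")

print()
print("Four utterances: the sentence-ending particle closes the first, the")
print("conjunction opens the second, the second conjunctive suffix closes it,")
print("and the 2.5 s pause splits the remainder.")
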