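"""Informativeness and productivity measures for one trial.

Builds a miniature one-minute picture-description trial and prints the
word-level measures: words and CIUs (intelligible words that are also
accurate/relevant/informative, per coder annotation), CIUs per minute,
and noun/verb tokens and types per utterance.
"""

from prespeech import Token, TrialRecord, Utterance
from prespeech.metrics import cius_per_minute, lexical_counts, nv_counts, words_per_minute


def tok(lemma, pos, onset, ciu=True, intelligible=True):
    return Token(surface=lemma, lemma=lemma, pos=pos, intelligible=intelligible,
                 ciu=ciu, onset_ms=onset, offset_ms=onset + 300)


utterances = [
    Utterance(index=0, tokens=[
        tok("dog", "common_noun", 0),
        tok("bark", "main_verb", 400),
    ]),
    Utterance(index=1, tokens=[
        tok("dog", "common_noun", 2000),          # repeated lemma: token, not new type
        tok("um", "other", 2400, ciu=False, intelligible=False),  # filler: not a word
        tok("run", "main_verb", 2800),
        tok("give", "aux_verb", 3200, ciu=False),  # counted word, not a CIU
    ]),
]

trial = TrialRecord(participant_id="demo", group="younger", picture_id="beach",
                    task_duration_ms=60_000, utterances=utterances)

words, cius = lexical_counts(trial)
nv = nv_counts(trial)
print(f"words = {words}, CIUs = {cius}")
print(f"CIUs/min = {cius_per_minute(trial):.1f}, WPM = {words_per_minute(trial):.1f}")
print(f"nouns: {nv.nouns_token} tokens / {nv.nouns_type} types "
      f"-> {nv.nouns_token_per_utt:.1f} and {nv.nouns_type_per_utt:.1f} per utterance")
print(f"verbs: {nv.verbs_token} tokens / {nv.verbs_type} types "
      f"-> {nv.verbs_token_per_utt:.1f} and {nv.verbs_type_per_utt:.1f} per utterance")
print()
print("The filler never enters the word count; the auxiliary verb counts as a")
print("verb token/type; the repeated 'dog' adds a token but no new type.")
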