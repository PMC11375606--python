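# prespeech

Connected-speech analysis for picture-description eye-tracking studies:
word-level informativeness and productivity measures, gaze–speech
temporal alignment, and the mixed-design ANOVAs used to compare age
groups across picture types. The package targets researchers in
psycholinguistics and cognitive aging who work with timed, token-
annotated transcripts (e.g. segmented in Praat) and EyeLink-style
fixation reports, and who want the whole measurement chain — from raw
transcripts and fixations to effect sizes — scripted and reproducible.

## What it computes

**Utterance segmentation.** Coder-annotated token streams are segmented
by the Korean connected-speech conventions: break after a
sentence-ending particle (unless contextually connected to what
follows), before a conjunction, after a silent pause of more than 2 s,
and — when speech runs through a conjunctive suffix — at the first
intonation shift or long pause, else at the second suffix.

**Informativeness and productivity.** For a trial of duration *T* (ms)
with word count *W* (intelligible tokens) and CIU count *C* (Correct
Information Units: words that are also accurate, relevant and
informative about the picture; C ≤ W):

    CIUs/min = 60000 · C / T        WPM = 60000 · W / T

Noun (common + proper + pronoun) and verb (main + auxiliary) tokens and
types (distinct lemmas per trial) are each normalised by the number of
utterances.

**Pre-speech fixations.** Utterance *i* with AOI label *a(i)* has the
planning window W_i = [onset(u_{i-1}), onset(u_i)) (the first window
starts at picture onset). Its pre-speech fixation count and duration
are

    n_i = #{f : AOI(f) = a(i), onset(f) ∈ W_i}
    d_i = Σ duration(f) over the same fixations

aggregated as Σn_i / N_AOI and Σd_i / N_AOI over the N_AOI AOI-related
utterances (utterances not about any AOI contribute neither counts nor
denominator). AOI membership is point-in-polygon with an optional
uniform outward buffer.

**Inference.** Split-plot ANOVAs for a two-level between factor (group,
unequal n allowed) crossed with one or two two-level within factors
(picture; part of speech), reporting per effect SS, df, F, p and
partial eta squared η_p² = SS_effect / (SS_effect + SS_error), which for
1-df effects equals F / (F + df_error). Independent-samples t-tests
(pooled or Welch) cover the speech-rate control analysis.

**Synthetic cohort.** Because the motivating study's participant data
are unavailable, `prespeech.cohort` generates two groups (24 younger,
22 older by default) × two pictures with configurable group/picture
effects on all five dependent measures and eye-voice-span-coupled
fixations, so the full pipeline is testable end to end and power and
sign recovery can be checked by simulation.

## Worked example

`examples/03_prespeech_fixations.py` builds a two-utterance trial over
the packaged Beach AOI polygons and scores it:

```
utterance 0 (barking_dog): window [0, 2000) ms -> 2 pre-speech fixations, 900 ms
utterance 1 (sea): window [2000, 5000) ms -> 1 pre-speech fixations, 1100 ms
aggregates: 1.5 fixations/utterance, 1000.0 ms/utterance
```

Both fixations on the dog AOI start before the dog utterance inside its
planning window (500 + 400 ms), the sea fixation precedes the sea
utterance, and a fixation outside every AOI never counts. The
aggregates divide by the two AOI-related utterances.

`examples/04_mixed_anova.py` runs the full study analysis on the
default synthetic cohort (seed 1) and prints, among others:

```
ANOVA for cius_per_min:
  group: F(1,44) = 42.235, p < 0.001, ηp² = 0.490
  picture_id: F(1,44) = 47.644, p < 0.001, ηp² = 0.520
  picture_id:group: F(1,44) = 1.187, p = 0.282, ηp² = 0.026
```

i.e. at the study's design (24 + 22 participants, two pictures within
subject) every 1-df effect is tested against 44 error df, and the
configured group and picture effects on CIUs/min are recovered as
significant while the (unconfigured) interaction is not.

The other examples cover segmentation (`01`), the word-level measures
(`02`), and a parameter-recovery experiment (`05`). A thin CLI mirrors
the library: `prespeech simulate | segment | metrics | gaze | stats |
run | recover`.

## Layout

- `src/prespeech/` — domain types and I/O (`types`, `io`), segmentation
  rules (`segmentation`), word-level measures (`metrics`), AOI/gaze
  alignment (`gaze`), mixed ANOVA and t-tests (`stats`), synthetic
  cohort (`cohort`), orchestration (`pipeline`), CLI (`cli`).
- `src/prespeech/data/` — packaged AOI configurations. Labels and
  agent/object roles follow the published 12-AOI inventories; vertex
  coordinates are synthetic stand-ins (see `docs/methods.md`).
- `docs/methods.md` — models, conventions, generator design, numerical
  choices and known limitations.
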