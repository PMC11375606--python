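# Methods

This note documents the measurement model the package implements, the
conventions chosen where the underlying procedures are underspecified,
the design of the synthetic cohort generator, and the limits of what
the simulation-based tests can show.

## Clocks, units, coordinates

All times are integer milliseconds on a per-trial clock with picture
onset at t = 0; a 1,000 Hz eye tracker makes milliseconds exact, so no
sub-millisecond arithmetic is attempted. Gaze positions are screen
pixels with the origin at the top-left of the 1680 × 1050 display,
x rightward and y downward. Utterance timing (onsets/offsets measured
upstream, e.g. in Praat) is input, never computed.

Token annotations — part of speech, intelligibility, CIU status,
sentence-ending particles, conjunctions, conjunctive suffixes,
intonation shifts, contextual connection — are human (or generator)
judgments carried on the input. The pipeline never infers them from
orthography or audio; Korean morphological analysis is out of scope.

## Utterance segmentation

The rule engine walks the junctions between consecutive tokens and
closes the current utterance when any rule fires:

1. after a sentence-ending particle, unless the coder flagged the
   token as contextually connected to what follows;
2. before a conjunction (a conjunction opens a new utterance that runs
   to the next sentence-ending particle — the engine reads this as
   also closing the preceding utterance, an interpretation documented
   here because the convention leaves it open);
3. after a silent pause strictly greater than the threshold (default
   2000 ms; exactly 2 s does not split);
4. within a conjunctive-suffix continuation, at the first intonation
   shift or over-threshold pause, else after the second conjunctive
   suffix. The suffix counter resets at every utterance boundary, i.e.
   "second suffix" is read within-utterance.

When several rules fire at one junction the boundary is the same, so
precedence is immaterial to the output. The engine guarantees token
conservation (concatenating the output reproduces the input), which
makes re-segmentation idempotent.

## Word-level measures

Words are tokens intelligible in context; CIUs are the flagged subset
that is additionally accurate, relevant and informative (enforced as
ciu ⇒ intelligible at construction). Rates divide by task duration in
minutes. Noun and verb tallies are restricted to intelligible tokens
for consistency with the word-count universe; nouns comprise common
nouns, proper nouns and pronouns, verbs comprise main and auxiliary
verbs. Types are distinct lemmas per trial and word class. Lemma-based
type counting is the default because inflection would otherwise
inflate type counts in an agglutinative language; surface-based
counting is available (`nv_counts(trial, by="surface")`) since the
original tallying convention does not state the key. Per-utterance
normalisation divides by the trial's total utterance count.

## Pre-speech fixations

The statistic operationalises incremental planning: while utterance
i − 1 is spoken, the speaker is assumed to plan utterance i, so the
planning window for utterance i runs from the onset of utterance i − 1
to the onset of utterance i. Conventions:

- **First utterance** (no predecessor): the window starts at picture
  onset, [0, onset(u_0)) — planning of the first description begins
  when the picture appears.
- **Half-open windows**: a fixation starting exactly at an utterance
  onset belongs to the next window. Windows therefore tile
  [0, last onset) exactly.
- **Membership and credit**: a fixation belongs to a window if its
  onset lies inside, and its full duration is credited (fixations are
  atomic events in Data-Viewer-style reports). The alternative
  `membership="truncate"` clips credited duration at the window end
  for fixations that straddle it; whether the original procedure
  truncated is not stated, so both are exposed and the default is the
  atomic reading.
- **Denominator**: only AOI-related utterances are scored; per-
  utterance counts and summed durations are aggregated and divided by
  the number of AOI-related utterances. With zero AOI-related
  utterances the aggregates are undefined and reported missing (NaN),
  never zero.
- **Shared AOIs**: consecutive utterances about the same AOI each get
  their own window under the same matching rule.

AOI hit-testing counts the polygon boundary as inside and supports a
uniform outward buffer emulating enlarged freehand AOIs. The packaged
configurations reproduce the two published 12-region inventories
(9 active agents / 3 static objects for the Han River picture, 6/6 for
the Beach picture), but the study's polygon coordinates were never
published: the packaged vertices are synthetic stand-ins on a
non-overlapping grid, pre-buffered, and every file says so. Results on
real stimuli require the laboratory's own AOI files.

## Mixed-design ANOVA

Supported designs are split-plots with one two-level between-subjects
factor (unequal group sizes allowed) and one or two two-level
within-subjects factors, fitted by the classical univariate
decomposition with subjects nested in group:

- the between effect is the one-way ANOVA on subject means (its F
  equals the squared pooled t on those means), tested against
  subjects-within-groups with N − 2 df;
- each within family — a main effect or pure within interaction plus
  its group interaction — lives in the subspace of one per-subject
  contrast score and is tested against its own
  factor × subject(group) stratum, also N − 2 df.

With unequal group sizes the within main effects differ between
observation-weighted and unweighted (cell-means) marginal means. The
package uses the weighted (hierarchical) decomposition: it is the one
under which the stratum sums of squares add exactly to the total sum
of squares (verified to 1e-8 relative tolerance in the tests), and
under the null both versions are exact F(1, N − 2) tests, so size and
calibration are unaffected. All within factors have two levels, so
sphericity holds trivially and no correction is implemented. Degenerate
inputs (constant dv ⇒ zero error SS) report F and p as missing rather
than raising.

Partial eta squared is computed from sums of squares,
SS_e / (SS_e + SS_err); `partial_eta_from_F` implements the equivalent
F·df1 / (F·df1 + df2) used to recover effect sizes from printed F
statistics, and the two are asserted identical for every 1-df effect.
p-values are carried at full precision; 3-decimal display is
formatting only.

## Synthetic cohort generator

The generator emulates the study's data *structure* — two groups
(24/22) × two pictures, utterance/token streams with coder-style
annotations, and gaze coupled to speech — not its unpublished values.
No distributional summaries of any dependent measure were reported, so
all magnitudes are free parameters with defaults chosen once:

- **Timing**: lognormal utterance durations (median 3 s, log-sd 0.35)
  and exponential inter-utterance gaps (mean 0.8 s) — positive,
  right-skewed, standard for speech timing. Initial delay ~1.5 s plus
  an exponential gap.
- **Tokens**: ~8 per utterance (younger), multinomial part-of-speech
  mix (45% noun / 30% verb classes), intelligibility 0.95, CIU
  probability 0.75; lemmas come from closed per-AOI and general
  vocabularies so type/token dynamics emerge from repeated draws. No
  natural language is generated.
- **Gaze**: each AOI-related utterance gets one planned fixation
  inside its AOI, landing one eye-voice span (mean 1000 ms, the
  canonical ~1 s gaze-to-name lag) before the utterance onset and
  releasing ~650 ms before it, so fixation duration = span − release
  and lengthening the configured span lengthens recovered pre-speech
  durations. Poisson "extra" target fixations (rate 0.3) and ~1 Hz
  background fixations complete the stream. Background fixations are
  constructed never to fall inside an upcoming utterance's AOI during
  its planning window, which gives the recovered pre-speech statistics
  closed-form expectations ((1 + extra rate) per utterance in count,
  times the mean planned duration in ms) that the calibration tests
  check against the measured pipeline output.
- **Effects**: switches apply the study's direction pattern — older
  adults: lower CIU probability (−0.08), fewer tokens per utterance
  (−1.5), longer eye-voice span (+80 ms); Han River: more utterances,
  more tokens, higher CIU probability; and a count interaction (extra
  fixation rate +0.8 for older × Han River only). Magnitudes were set
  a priori at roughly one between-subject standard deviation so that,
  as in the study, effects are detectable at n = 24/22; they are not
  estimates of the real effect sizes.

Participant-level random effects (token rate, CIU probability, span)
induce realistic between-subject variability. Generation is fully
deterministic given the seed. Impossible geometry/timing (an eye-voice
span longer than its window) is clamped and counted in a warnings
dictionary, never silently invalid.

What the generator does *not* emulate: real lexical content and
discourse structure, saccades/blinks/smooth pursuit, drift and
calibration error, coder disagreement, and any correlation structure
between linguistic and gaze measures beyond the built-in couplings.
Passing recovery tests therefore show that the measurement chain and
inference are correct and well calibrated on data satisfying the
stated assumptions — not that the assumptions hold for any real
cohort.

## Problem sizes used in validation

The oracle comparisons run 1,000 random annotated streams
(segmentation), 500 random trials (pre-speech scoring), and 3,000
random points (AOI assignment). ANOVA calibration uses 2,000 null
replicates at the study's 24/22 design with the sum-of-squares
partition checked on every replicate. The recovery experiment uses 25
full generate–measure–test replicates of the complete cohort, enough
to resolve power > 0.8 clearly at the configured effect sizes.

## Known limitations

- Packaged AOI polygons are synthetic stand-ins; any spatial statistic
  on them is illustrative only.
- The 2 × 2 (× 2) designs are hard-wired; factors with more than two
  levels (and hence sphericity corrections) are unsupported.
- Pre-speech scoring assumes one observation stream per trial; no
  handling of blinks or track loss beyond off-screen flagging.
- The segmentation engine follows the documented reading of the
  conjunction rule (a conjunction also closes the preceding
  utterance); corpora annotated under a different reading will diff.
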