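# Methods

This note documents the models, parameters and design choices behind
`speechscreen`, and what the synthetic experiments do and do not show.

## Audio contract and power normalization

The pipeline's canonical signal is mono RIFF WAV at 16 kHz; integer PCM
(8/16/32-bit) and float WAV dialects are accepted and represented internally
as float64 amplitudes in [−1, 1]. Multi-channel input is averaged to mono.
Input at another rate is polyphase-resampled to 16 kHz with a logged
warning rather than rejected, because field recordings vary.

"Power normalization" is implemented as scaling each utterance to a fixed
target RMS (default 0.1), applied per utterance. Peak normalization was
rejected as less robust to clicks and onset transients. The operation is a
pure gain: it preserves waveform shape exactly, is idempotent to 1e-9, and
fails loudly (rather than dividing by ~0) on signals with RMS below 1e-12.

## MFCC front end

No single "standard" MFCC parameterization exists, so the defaults follow
common speech front-end practice and are all configurable:

| parameter | default | note |
|---|---|---|
| frame length | 25 ms | Hamming window |
| frame hop | 10 ms | → 100 frames/s modulation sampling rate |
| FFT length | next power of two ≥ frame (512 @ 16 kHz) | |
| mel filters | 26 | unit-peak triangles, 0 Hz–Nyquist |
| coefficients | 13 incl. c0 | DCT-II, orthonormal |
| pre-emphasis | 0.97 | |
| log floor | 1e-12 | keeps silence finite |

The implementation is vectorized numpy/scipy; the test suite checks it to
1e-6 against an independently coded, loop-style reference implementation
written directly from the textbook definitions.

## Modulation spectrum and feature selection

For each cepstral coefficient, the trajectory is mean-removed (so the DC
bin does not swamp the spectrum), zero-padded to a fixed analysis length of
512 frames (~5.12 s at the 10 ms hop), transformed with a real DFT along
time, squared, and floored at 1e-12 before the log. The fixed analysis
length makes modulation bins comparable across utterances of different
durations; utterances longer than the pad are truncated with a warning
(responses to the ~20 s screen contain only a few seconds of speech).

The classifier's acoustic features are the *coefficient-averaged* log
power at the 20 lowest non-DC modulation bins — 0.195…3.906 Hz at the
defaults — a fixed-length, utterance-comparable summary of syllable-rate
and pausing dynamics. An alternative reading, per-coefficient low-order
components, would give a 13×20 feature block; the aggregated form was
chosen because it yields the fixed 22-feature vector the classifier
expects and is robust to coefficient-specific noise. Useful invariances,
all property-tested: circular time shifts leave the features unchanged
(power discards phase); scaling the MFCCs by c shifts every non-floored
log-power bin by exactly 2·log c; the fast transform matches a brute-force
O(N²) DFT to 1e-9 and satisfies Parseval's identity.

## Orientation scoring

The spoken answer is scored 0–4: one point each for the correct
Western-calendar year, month, day-of-month and weekday found in the
transcript. The element set and 1-point-per-element rubric follow the
time-orientation item of standard screening scales; exact match is
required (no ±1-day tolerance), and the reference date is an explicit
argument so scoring never depends on the wall clock.

Matching is set-based on normalized text (NFKC, case-folded): an element
is *correct* only if its candidate set is exactly the reference value,
*incorrect* if any wrong candidate appears, *absent* otherwise. This makes
the score an order-free sum of four indicators and monotone under adding
correct elements. Locale rules are JSON data files: English rules are
token-based with numeral-word and ordinal support ("twenty fifth" = 25,
"30th" = 30); Japanese rules are pattern-based on the 年/月/日/曜 suffixes
(kanji numerals are not parsed — a known limitation). In English, months
are matched by name only; bare small integers are treated as day-of-month
candidates, so numeric-only dates like "25 9 2025" under-credit the month.

Speech-to-text is a pluggable interface. The shipped backends are a mock
(fixed id → text) and a sidecar-file reader; a cloud recognizer can be
registered at run time. Recognition quality is explicitly out of scope.

## Classifier

`sklearn.ensemble.GradientBoostingClassifier` over the canonical
22-vector (age, score, ms_01…ms_20), dementia encoded as the positive
class. Defaults: 300 trees, depth 3, learning rate 0.05 — conservative
settings for small tabular problems — with subsampling off; all exposed.
The decision threshold is 0.5 with P ≥ threshold → dementia (the operating
point is not otherwise constrained). Training requires both classes with
at least 10 examples each and is deterministic for fixed data, settings
and seed. Models persist as a joblib binary plus a JSON sidecar carrying
the format version, hyperparameters, feature signature, seed and
threshold; loading verifies the version and the signature guards against
feature-order mismatches.

There are no published trained weights; all training in this repository is
on synthetic cohorts, and field accuracies on clinical audio are
explicitly not claimed (see "What the synthetic experiments show").

## Exact tests and reporting

Percentages are reported as numerator/denominator with the percent rounded
half-up to one decimal. Zero-denominator strata report n/a instead of
raising. Sensitivity and specificity are defined on the dementia and
cognitively-normal groups respectively; age stratification uses decade
bins [20,30)…[90,100).

Fisher's exact test is implemented as one engine for r×c tables: condition
on the observed margins, enumerate every table (depth-first over cells,
incremental log multivariate-hypergeometric probabilities), and sum the
probabilities of tables no more probable than the observed one, with a
1e-7 relative slack for floating-point ties. This probability-mass
two-sided rule is the convention of R's `fisher.test`, against which the
implementation is verified. The 2×2 case is the same engine; tests check
it against exact rational-arithmetic enumeration and scipy. Enumeration
beyond a configurable budget (default 2·10⁶ tables) raises an error
suggesting the seeded Monte-Carlo fallback, which samples tables with the
observed margins by random pairing of the row/column category labels.

The between-facility comparison is a single 3×2 exact test per metric on
correct/incorrect counts by facility — matching the single printed p-value
per metric — rather than pairwise tests; the per-stratum association test
is the 2×2 diagnosis-vs-prediction table. With the published counts these
give p = 0.015 (accuracy), p = 0.010 (sensitivity), p = 0.058
(specificity, not significant), and p < 0.001 for every association table.

## Synthetic cohorts

The generator reproduces the study conditions it can know:

* **Strata** — facility × diagnosis sizes and age mean ± SD as published
  (pooled: 489 dementia aged 79.9 ± 8.7; 1097 normal aged 73.9 ± 13.1).
  Ages are truncated normal on [20, 100); the real age distribution is
  skewed, which is not modeled — a deliberate simplification.
* **Orientation behaviour** — each element is independently flipped to a
  wrong value with probability 0.45 (dementia) vs 0.05 (normal), and the
  transcript is rendered from the flipped values, so transcript and score
  are mutually consistent by construction.
* **Audio** — band-limited noise (300–3000 Hz) gated by raised-cosine
  syllable bursts: rate 3.5 Hz with 35% pauses (dementia) vs 5.5 Hz with
  15% pauses (normal), ±30% per-syllable amplitude jitter, 4 s default
  duration, power-normalized. The envelope's modulation peak lands within
  one bin of the syllable rate, which is exactly what the low-order
  modulation features measure.

Effect sizes and directions (slower, pause-heavier, more error-prone
responses in the dementia class) are chosen so that desk-scale training
succeeds; the pause fractions are the package's own choice, as no such
value is published. A zero-effect null configuration equalizes everything
between the labels for leakage testing.

`table2_fixture()` is different in kind: it is an *exact* reconstruction
of the published predictions table — 1586 rows whose per-facility
confusion counts are forced by the printed fractions (e.g. facility A
false positives = 498 − 486). Counts, not individuals, are the contract;
ages are drawn synthetically from the stratum moments (misclassified rows
at ages ≥ 50, keeping the per-decade error profile plausible), since no
per-subject data exist.

### What the synthetic experiments show — and do not

Problem sizes used in the shipped checks: end-to-end recovery trains on a
balanced 200-per-class cohort (seed 42, 70/30 split) and reaches held-out
accuracy ≥ 0.90; the null check averages 20 seeds of the same size and
stays at 0.50 ± 0.05. Together these show the pipeline transmits exactly
the class signal the generator injects, and nothing else (no leakage
through featurization, splitting or training). They do **not** validate
the published field accuracies: synthetic bursts are not Japanese speech,
orientation errors are independent Bernoulli flips rather than real
response behaviour, and transcription is mocked. Reproducing the clinical
operating characteristics would require the original recordings.

## Known limitations

* English numeral parsing does not handle spoken year forms like
  "twenty twenty-two"; Japanese rules need ASCII/full-width digits.
* The modulation feature band (≲3.9 Hz at the defaults) sits below typical
  healthy syllable rates; the features still separate classes through
  band-edge energy and pause structure, but the band is a configuration
  choice, not an optimum.
* The exact 2×2 tables behind the published per-facility "p < 0.001"
  association claims are not printed; the diagnosis-vs-prediction reading
  used here reproduces them qualitatively (all ≪ 0.001) and reproduces the
  printed between-facility p-values exactly.
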