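# Methods

`corticolfp` re-implements, as a tested pipeline, an analysis linking
corticostriatal local field potential (LFP) oscillations to a high- vs.
low-alcohol-drinking phenotype in rats: four channels (bilateral nucleus
accumbens shell, NAcSh, and medial prefrontal cortex, mPFC) recorded at
2 kHz are reduced to 60 spectral features per animal, animals are labeled
HD/LD by a median split of training consumption (g/kg), a lasso logistic
classifier is benchmarked against a label-permutation null, and the
response to stimulation is tested with a 2x2 mixed ANOVA. Because no raw
recordings are publicly available, a synthetic cohort generator with
known ground truth drives every stage.

## Synthetic data model

Each channel is the sum of

- **pink background noise** (1/f amplitude shaping of white noise,
  RMS 0.2 mV by default), and
- **one band-limited Gaussian process per frequency band**, realized by
  zero-phase 4th-order Butterworth band-pass filtering of white noise,
  RMS 0.05 mV at 0 dB. A subject's `band_power_offsets` scale each
  band/channel process in dB.

Inter-channel coherence is injected per channel pair and band by a mixing
weight `w` in [0, 1]: the band process becomes
`sqrt(1 - w) * independent + sqrt(w) * shared`, so the expected
magnitude-squared coherence contributed by the band is `w**2` — zero at
`w = 0`, monotone in `w`, and 1 at `w = 1` when the background is zero.

Artifacts are half-sine transients of 20 ms width and configurable peak
amplitude, Poisson-placed in time on random channels; ground-truth event
times are kept in the recording's metadata so rejection can be audited.

Drinking tables draw each subject's session consumption from a normal
distribution (clipped at zero) around a subject mean: LD subjects 0.7
g/kg with 0.2 g/kg session noise by default (a realistic limited-access
intake level), with cohort-level effects for the HD group (training-mean
offset, extra gamma power/coherence, and a consumption drop during
stimulation sessions).

Defaults mirror the study design: 13 subjects (7 HD / 6 LD), two 30-min
recording sessions at 2 kHz, 12 training and 3 stimulation drinking
sessions. The generator emulates stationary band-structured noise; it
does **not** model non-stationarity, behavioral state changes,
volume conduction, electrode drift, or cross-frequency coupling, so
passing tests demonstrate the correctness of the pipeline's algebra and
its recovery of injected effects — not performance on real recordings.
The millivolt amplitude scale is a stand-in; the source study reports no
amplitude statistics.

## Preprocessing

Notch -> decimate -> threshold -> epoch, in that order:

1. **Notch**: Chebyshev type I band-stop, design order 4, stop band
   59–61 Hz, applied forward-backward (`sosfiltfilt`) for zero phase.
   Default passband ripple is 0.25 dB: the two-pass application squares
   the response, so this keeps the net passband loss at or below 0.5 dB
   (a 1 dB design would cost ~2 dB). At 60 Hz the attenuation is
   hundreds of dB.
2. **Decimation** by 5 (2 kHz -> 400 Hz) with `scipy.signal.decimate`'s
   anti-alias filtering. Artifact detection operates on the decimated,
   filtered signal.
3. **Artifact mask**: any sample on any channel at or beyond ±2 mV marks
   an event; the interval from 12.5 ms before to 1 s after each event is
   excised, clipped to the recording and merged across overlaps. The
   mask is global across channels so coherence sees identical clean time
   everywhere. Intervals are half-open, 0-based sample indices;
   seconds-to-samples conversion rounds to the nearest sample.
4. **Epochs**: each maximal clean run yields `floor(run / 3 s)`
   non-overlapping 3 s epochs from the run's start; remainders are
   dropped. Total analyzed time is *not* equalized across subjects.

## Spectral features

Per epoch, Welch PSDs use a 1.28 s Hamming window with 50% overlap
(0.78125 Hz grid at 400 Hz); per-epoch PSDs are averaged in the linear
domain into one session spectrum, then converted to dB. Spectra are
expressed in **dB re 1 µV²/Hz** (recordings are in mV): for
physiological amplitudes this keeps the broadband dB average positive,
which the percent normalization below requires — with a negative
normalizer the direction of every power feature would invert.

Magnitude-squared coherence uses the same windowing per epoch and is
averaged across epochs. With ~3 windows per 3 s epoch the estimator
carries the familiar small-sample positive bias (~1/L); this bias is
shared by all subjects and cancels in group comparisons.

Band summaries average the dB spectrum (power) or coherence spectrum
over the band's grid bins — delta 1–4, theta 5–10, alpha 11–14, beta
15–30, low gamma 45–65, high gamma 70–90 Hz — excluding bins in
(59, 61) Hz, and are normalized as a percent of the same average over
the full 1–90 Hz range (same exclusion). A bin belongs to a band when
`low <= f <= high`; bins in the 4–5 and 30–45 Hz gaps count only toward
the normalizer. Averaging in the dB domain is the default
(`power_domain="linear"` is available). Per-session 60-entry feature
vectors (24 power = 4 channels x 6 bands; 36 coherence = 6 pairs x 6
bands) are combined across the two sessions by entrywise arithmetic
mean.

## Phenotype statistics

- **Median split**: subjects at or above the median of their last-3
  training-session averages are HD; for odd n the median subject lands
  in HD (13 -> 7/6). The partition is invariant to strictly monotone
  transforms of the values.
- **Group comparison**: pooled-variance two-sample t, df = n - 2.
- **Stimulation response**: 2 (phase: training vs. stimulation, within)
  x 2 (group, between) mixed ANOVA from the weighted-cell-means
  split-plot decomposition; every effect is tested on (1, n - 2) df and
  reported with partial eta squared = SS_effect / (SS_effect +
  SS_error). With two within levels the interaction F equals the
  squared pooled t on difference scores; the implementation agrees with
  `pingouin.mixed_anova` to machine precision on unbalanced data. The
  three stimulation sessions are averaged per subject before the ANOVA.
  No sphericity correction is needed with two within levels; no
  multiple-testing correction is applied.

## Classification

L1-penalized logistic regression (lasso), evaluated by repeated 4-fold
cross-validation (100 repetitions by default). Folds are drawn uniformly
at random each repetition and re-drawn if any training set lacks a
class; they are deliberately *not* stratified — the chance level of
repeated CV on a 7/6 cohort reflects the negative correlation between a
training fold's class balance and its held-out subjects, which
stratification would suppress. Within each training fold, features are
standardized (scaler fit on the training fold only) and the penalty
strength is chosen by inner 3-fold cross-validation minimizing mean
binomial deviance over a 15-point logarithmic C path (1e-2 to 1e2),
ties broken toward the stronger penalty. Held-out subjects are
classified at probability threshold 0.5 (ties toward HD); accuracy pools
the held-out predictions of one repetition, and the model's accuracy is
the mean over repetitions.

The permutation null shuffles the class labels (features untouched) and
re-runs the entire procedure per permutation (100 by default); the null
distribution collects per-permutation mean accuracies. Real and null
distributions are summarized by means and 95% percentile intervals; the
model "outperforms chance" when its mean exceeds the null 97.5th
percentile. On null cohorts the permuted mean sits near 50% (the spread
of per-permutation means is ~8 percentage points, so estimates based on
tens of permutations carry 1–2 points of Monte-Carlo error).

Single-feature information content: every feature is evaluated alone
with unpenalized logistic regression under the same repeated-CV scheme
and compared against its own label-permutation null; a feature is
flagged informative when its real mean accuracy exceeds its null 95th
percentile (an ~5% per-feature type-I rate), and features are ranked by
real mean accuracy.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; results are bit-reproducible, including
liblinear's internal shuffling (fixed `random_state`).

## Problem sizes

The test suite and `scripts/acceptance.py` use scaled-down problem
sizes chosen as a deliberate trade-off: recordings of 30–60 s per
session instead of 30 min (spectral estimates are noisier but unbiased,
and the permutation chance level does not depend on recording length),
and permutation benchmarks of 20–50 permutations x 10–20 repetitions
instead of 100 x 100. The full-size defaults remain in `PipelineConfig`.

## Known limitations

- The generator's stationary, additive band model cannot probe
  robustness to real-world non-stationarity or referencing artifacts.
- dB-domain percent normalization assumes a positive broadband dB mean
  (satisfied for µV-referenced physiological spectra); degenerate
  spectra are rejected rather than silently normalized.
- The per-feature significance rule is a concrete choice among several
  defensible ones; its type-I rate is controlled per feature, not
  family-wise.
- With 13 subjects, CV accuracy distributions are coarse (1/13 grid per
  repetition); percentile intervals inherit that granularity.
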