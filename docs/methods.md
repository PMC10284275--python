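# Methods

## Scope and model

`elevdec` decodes a continuously crowd-tagged social emotion from EEG.
The target signal y is a per-second emotion score derived from
time-stamped viewer comments; the predictors X are per-second EEG band
powers averaged across participants ("group-level" features, appropriate
because the tag reflects a population's shared experience rather than any
individual's). The decoder is an L1-penalized linear model

    ŷ = wᵀx + b,   w = argmin ‖y − Xw − b‖² + λ‖w‖₁,

chosen for interpretability and for the p ≈ n regime (128 features,
300 s of data).

## Comment scoring

The dictionary maps terms to intensity scores in {0, 1, 2}; raw mean
Likert ratings in [1, 7] are re-coded with cut points 2.5 and 5.5, the
middle band closed at both ends so the three rules are exhaustive and
mutually exclusive. Scoring of a comment stream:

* Text is scanned left to right with greedy longest-match against the
  union of entry, negator and degree-word lexicons, case-insensitively;
  unmatched spans are skipped. A pluggable tokenizer hook accepts an
  external segmenter (needed for languages without whitespace word
  boundaries); the hook's output units are matched against the lexicons
  whole.
* Modifier scope: negators (weight −1) and degree words (×0.75, ×1.25,
  ×1.5, ×2 by default) accumulate multiplicatively and attach to the next
  entry term within the same comment; an entry term consumes the pending
  modifiers; modifiers with no following entry term contribute nothing.
  This is the simplest rule consistent with phrases like "not very
  touching" (weight −1.5).
* Binning: second *i* covers [i, i+1); integer timestamps fall into the
  later window. The per-second weighted token-score sum is divided by the
  video's **total** comment count N, which normalizes videos of different
  popularity; comment density within a second then contributes through
  the number of summed tokens, as intended.
* Series from multiple videos are z-scored **jointly** (one mean and one
  SD over all 1-s segments, population convention so the output SD is
  exactly 1). No smoothing is applied by default; a centered per-video
  moving average of configurable width is available.

## EEG features

Preprocessing is zero-phase throughout: a 50-Hz notch (quality factor 30,
forward-backward with ~3 s padding), then the 0.05–47 Hz band limitation
implemented as a 4th-order Butterworth high-pass at 0.05 Hz run with
Gustafsson's initial-condition method and a 4th-order Butterworth
low-pass at 47 Hz. The cascade matters: a single band-pass with a 0.05 Hz
edge has a multi-second settling time that dominates any practical
padding, measurably leaving only ~7–12 dB of 50-Hz RMS rejection on test
sinusoids, whereas the cascade achieves >25 dB. An optional
`artifact_hook` slot accepts an ICA-style cleaning stage; it is disabled
by default because the synthetic data contains no ocular artifacts.

Band decomposition uses 4th-order Butterworth band-passes (theta 4–7,
alpha 8–13, beta 14–29, gamma 30–47 Hz, sosfiltfilt). Per-second power is
the raw sum of squared samples over each non-overlapping 1-s window (a
unit-amplitude in-band sinusoid at 250 Hz gives ≈ 250/2 = 125 per
second); a trailing partial second is dropped. Columns are ordered
channel-major (ch1-theta, ch1-alpha, …), the ordering written into output
headers. Powers are used untransformed by default; a log10 switch exists.
Group features are the element-wise mean over participants of identically
labeled matrices.

The default 32-channel montage uses modern temporo-parietal names
(T7/T8/P7/P8) so that site names in coupling maps match common reporting.

## Decoding

* Penalty convention: with the squared-error term unscaled, the smallest
  all-zero penalty is λ_max = 2·max|X_cᵀ(y − ȳ)| (column-centered X);
  the sklearn coordinate-descent backend is driven with α = λ/(2n).
  λ = 0 is solved by least squares.
* NMSE = MSE / var(y_true) (population variance): predicting the mean
  scores exactly 1, a perfect prediction 0. This is the only convention
  under which an NMSE near 0.8 is coherent next to a CV r near 0.45.
* λ selection minimizes inner 5-fold cross-validated NMSE within the
  training portion, on a 50-point log grid from λ_max(training fold) down
  to 10⁻³·λ_max, ties broken toward the larger (sparser) λ. In-sample
  training NMSE would degenerate to λ → 0, so inner CV is the only
  self-consistent reading of "the λ that minimized NMSE in the training
  set".
* Features are z-scored per column with training-fold statistics
  (test folds transformed with the same parameters); the target is
  centered with the training mean. No statistic crosses the train/test
  boundary.
* Evaluation: repeated k-fold CV (5 folds × 100 repeats by default), each
  repeat a fresh random partition seeded deterministically from the
  master seed. Per fold we record the selected λ, test Pearson r, test
  NMSE and the support size. Folds whose prediction is numerically
  constant (the null model) have undefined r; they are recorded as NaN
  and excluded from r aggregation, with the count reported. Aggregates
  are reported both over all fold-level values and over per-repeat means.
* Inference caveat: fold-level r values across repeats are *not*
  independent — repeats re-partition the same data. Where the test suite
  asks whether a mean r differs from zero it either pools folds across
  independent simulated datasets or uses a conservative effective sample
  size equal to the fold count of a single repeat.
* The univariate map reports Pearson r and two-sided p per feature with
  Bonferroni significance at α/n_features; constant columns yield NaN.

## Synthetic data generator

The generator emulates the study inputs with a known ground truth; its
defaults are the reference conditions (23 participants, 32 channels,
250 Hz, videos of 136/84/80 s, ~60 comments/s, seven negative beta/gamma
couplings at Fz, F4, FC2, P7, P8 with |r| 0.22–0.28).

* **Latent trajectory**: per video, Gaussian noise smoothed with a 4-s
  Gaussian kernel plus 2–4 positive bumps (widths 8–15 s, amplitudes
  1–3), the concatenation standardized. Lag-1 autocorrelation exceeds
  0.9, emulating the slow multi-bump course of real continuous ratings.
* **Comments**: per second, Poisson(rate) comments of 1–3 dictionary
  terms; a term's score s ∈ {0,1,2} is drawn with probability
  ∝ exp(s·β·latent), β = 0.8, so high-intensity vocabulary becomes
  monotonically more likely as the latent rises; negators and degree
  words are prepended with probabilities 0.05 and 0.10. The default rate
  of 60/s mirrors the comment-density selection threshold of heavily
  commented videos. At these settings the scored series correlates with
  the latent at r ≈ 0.7–0.9.
* **EEG**: each channel is a sum over bands of band-limited noise
  (synthesized in the frequency domain with a flat in-band spectrum; RMS
  4/3/2/1.5 µV for theta/alpha/beta/gamma), broadband white noise (1 µV)
  and 50-Hz line interference (2 µV, random phase). Coupled
  (channel, band) components carry the per-second amplitude envelope
  1 + g·sign·latent. The gain g is solved per realization by Brent root
  finding so that the group-mean per-second power of that component
  correlates with the latent at exactly the requested effect_r; an
  effect_r beyond what a positive envelope can produce raises an error.
  The feature pipeline's own filtering shrinks the realized correlation
  by roughly 5% (e.g. −0.22 recovered for a planted −0.23). Random
  streams are keyed per (participant, channel), so synthesizing a channel
  subset is bit-identical to slicing the full montage — used to keep
  repeated recovery checks cheap without changing the generated data.
* **Self-report**: each rater's sliding-bar trace is the latent convolved
  per video with a causal Gaussian lag kernel (lag 2 s, width 1 s),
  mapped to the bar as 0.5 + 0.12·value, plus white noise (SD 0.1 bar
  units), clipped to [0, 1]; five raters by default. The comment-score
  vs. mean-trace correlation then falls in the 0.6–0.9 range.

What the generator does **not** emulate: volume conduction and channel
covariance, ocular/muscle artifacts, 1/f spectral slopes within bands,
non-stationary comment herding, or natural language (the vocabulary is a
60-term synthetic lexicon). Passing recovery tests therefore demonstrate
correctness of the pipeline's computations and calibration, not
performance on real recordings.

## Numerical and design choices

* All filters are Butterworth; zero-phase via forward-backward
  application. Padding is min(3 s, signal length − 1) samples.
* Population (ddof = 0) SD for z-scoring and NMSE; sample SD (ddof = 1)
  for reported across-fold dispersions.
* Per-stage random streams derive from the master seed through
  `SeedSequence`, making fixtures and decoding reports byte-identical
  across runs with the same seed (manifest checksums verify this).
* Degenerate inputs fail loudly: constant targets, zero-variance series,
  overlapping lexicons, misaligned shapes and non-finite samples raise
  typed errors naming the offender.
* The pipeline materializes every stage output as a file with a SHA-256
  manifest so stages can be re-run and audited independently.

## Problem sizes used in the test suite

Unit tests run on scaled-down configurations (2–3 participants, 4–8
channels, 20–55 s) chosen to exercise every code path quickly; the
end-to-end recovery and null-calibration tests run at the full default
scale (23 participants, 32 channels, 300 s), with 20 CV repeats, 20
recovery simulations and 200 feature-level null simulations — sizes at
which the checked effects are resolvable with comfortable statistical
margins.

## Known limitations

* The LASSO backend is coordinate descent (scikit-learn); an independent
  proximal-gradient implementation is used in the tests as an oracle, to
  1e-5 coefficient agreement.
* EDF input requires the optional `mne` dependency; the native exchange
  format is delimited matrices (or .npy) plus a channel-metadata CSV.
* Valence-style targets are supported generically (any per-second series
  can be decoded) but no second lexicon ships with the package.
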