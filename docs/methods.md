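# Methods

This note records the model, the defaults, and the design choices behind
`revcorr`, including the points where the procedure admits more than one
reasonable reading and what was decided.

## Stimulus space

The stimulus domain is a partition of [100, 13000] Hz into `b = 8`
contiguous rectangular bins of equal mel width. The mel convention is
O'Shaughnessy's, m(f) = 2595·log10(1 + f/700), the most widely used form;
the formula name is recorded in the partition's config block so an
alternate convention could be swapped in without ambiguity. Bins are
half-open [edge_k, edge_{k+1}) with the final bin closed, so every
in-range frequency belongs to exactly one bin. "Rectangular" is taken to
describe flat bin profiles (no tapering), not a constraint on edge
placement — the only reading consistent with mel spacing.

Each stimulus fills a uniformly drawn number of bins between 2 and 7
(count uniform on the integer interval, subset uniform without
replacement — the simplest model consistent with "2 to 7 bins randomly
filled") at 0 dB; unfilled bins sit at −100 dB. dB values are power dB,
so spectral magnitude is 10^(dB/20) and −100 dB means a 10⁻¹⁰ energy
ratio. The expected fill probability per bin is mean(2..7)/8 = 0.5625.

## Waveform synthesis

Sample rate defaults to 44.1 kHz, making a 500 ms stimulus 22050 samples
with 11025 positive-frequency samples in its one-sided spectrum. Each
positive frequency takes its bin's magnitude, an i.i.d. uniform [0, 2π)
phase, zero outside the partition range; DC and Nyquist are zeroed (no
phase freedom, inaudible). The real inverse FFT is peak-normalized to
|x| ≤ 1 rather than RMS-normalized: presentation level is uncontrolled in
the protocol (subjects set a comfortable level), and Pearson-r validation
is scale-invariant, so any monotone level choice leaves the analysis
unchanged. WAV export is mono IEEE float32 by default (PCM-16 optional).

## Targets

A target's validation reference `s` is its binned power spectrum: the
rectangular-window periodogram of the 500 ms (truncated, resampled if
needed) waveform in dB, averaged **in the dB domain** within each bin.
dB-domain averaging is used because displayed spectra are dB traces and
the validation statistic is scale-invariant; linear-domain averaging is
the main alternative and would shift bin values for spectra that vary
strongly within a bin.

No canonical "buzzing"/"roaring" recordings ship with the package, so
`synthesize_target` builds synthetic stand-ins from an explicit per-bin
dB profile: random-phase noise with deterministic per-bin magnitudes,
re-referenced by a constant dB offset (a choice of reference level) so
the analyzed binned spectrum reproduces the requested profile, verified
internally to 1 dB. The two packaged profiles are chosen only to be
spectrally complex and mutually complementary — "buzzing-like" has
interleaved mid/high-bin emphasis, "roaring-like" is low-frequency
weighted with a steep rolloff — and make no claim about any particular
recording. Conclusions drawn from them characterize the *method* on
multi-band targets, not any specific tinnitus sound.

## Observer model and estimator

The response model is y = sign(Ψx) with the tie sign(0) → +1, fixed
because exact zeros, while measure-zero for random stimuli, arise in
degenerate tests. The estimator is x̂ = (1/p)Ψᵀy, the response-weighted
mean stimulus. The divisor is the trial count p (the only count in
context); the scale is immaterial to correlation-based validation. Ψ is
*not* mean-centered before the product — the estimator is implemented
verbatim — but a centered variant is available behind a keyword
(`reconstruct(..., center=True)`), relevant because dB-coded binary
stimuli have nonzero column means.

The ideal observer answers +1 when a trial's similarity Ψᵢ·s (row i of Ψ
against the target spectrum) reaches the session median of Ψs; the median
uses linear interpolation between central order statistics, and threshold
ties answer +1. The similarity index is read over trials (rows), the only
dimensionally consistent interpretation. The random observer answers ±1
i.i.d. uniform. Repetitions of a simulated experiment use independent
child RNG streams spawned from a master seed, so results are reproducible
and independent of execution order.

## Validation statistics

Accuracy is the product-moment correlation r(x̂, s), degenerate (constant)
inputs rejected rather than silently returning NaN. Group tests Fisher-z
transform the per-subject r values, run a two-sided one-sample t-test
against zero on the z scale, and report mean/sd on the r scale. No
multiple-testing correction is applied across the per-target and combined
tests, matching the protocol's reporting convention. The two-way ANOVA
(subject + target factors on Fisher-z values) is additive: with one
observation per subject×target cell no interaction is estimable, and the
degrees of freedom follow the standard additive decomposition.

## Experiment protocol

Defaults: 100 trials per block, 2 blocks per target, 2 targets — p = 200
trials per target entering the estimator, 400 trials in a full two-target
session. The per-target p is always the session length used in Eq.
inversion; blocks, trials, and target list are independent config knobs
because the protocol's trial accounting can be read per-target or
per-session. Response logs accept {yes, no, y, n, 1, -1} case-insensitively;
anything else is a parse error — no silent coercion. Stimulus manifests
record the filled mask, per-bin dB, seeds, and a config hash; responses
join by stimulus id, so log row order is irrelevant. Audio presentation
(timing, calibration, playback) is out of scope: the package exports the
stimulus set and consumes the response log.

## Simulation scale and what it shows

The packaged benchmarks run the method at the study scale — p = 200,
b = 8, 1000 repetitions for the accuracy distributions, 200 repetitions
per trial-count point for recovery curves, 1000 ten-subject cohorts for
t-test calibration. At this scale the random observer's accuracy is
0.00 ± ~0.37–0.38 (mean ± sd; the spread is target-dependent), the ideal
observer reaches ≈ 0.90, estimator recovery of a hidden Gaussian template
exceeds 0.88 on average at p = 200, and the group t-test's empirical
type-I error is ≈ 0.05.

Passing these checks shows the machinery is correct and calibrated under
the generative model: stimuli exactly binary in the bin domain, responses
exactly following the sign/median/uniform policies. Real data differ —
human responses are noisy and criterion-shifting, real targets have
within-bin structure that an 8-bin summary flattens, and presentation
level varies — so simulated accuracies bound, but do not predict, human
accuracy.

## Known limitations

- Estimator variants (ridge, sparse, Bayesian RC) that improve efficiency
  are deliberately out of scope; only the plain estimator (with optional
  centering) is provided.
- The ideal observer's yes-rate is fixed at 0.5 by median thresholding;
  intermediate (noisy-ideal) observers are not modeled.
- Bark/ERB spacings and non-rectangular bin profiles are not implemented;
  the partition API isolates edge placement so they could be added.
- `load_target` assumes WAV input (float or integer PCM); compressed
  formats must be converted upstream.
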