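# Methods

This note documents the models, estimators and numerical choices behind
`betaburst`, in the spirit of a package reference manual: what is
computed, under which assumptions, and where genuinely open design
decisions were resolved.

## Signal model of the synthetic generator

The generator (`betaburst.synth`) emulates a paired STN LFP / cortical
ECoG recording at the level needed to validate burst-resolved coupling
analyses, not at the level of basal-ganglia biophysics.

**Background.** Each channel carries independent Gaussian noise spectrally
shaped to power ∝ f^(−noise_exponent) (default exponent 1), normalized to
unit variance and scaled by `noise_amp` (default 1). DC is removed.

**Beta component.** A narrowband oscillator with instantaneous phase
φ(t) accumulating 2π·(f_beta + ξ(t))/fs per sample, where ξ is white
Gaussian frequency noise with SD `freq_jitter_hz` (default 25 Hz). This
yields a Lorentzian beta peak with FWHM ≈ (2π·25/fs)²·fs/(2π) ≈ 4 Hz —
a linewidth consistent with 100–500 ms bursts (a much narrower peak would
imply coherence times longer than the bursts themselves) — so two
independent oscillators decorrelate within ~100 ms, as real beta rhythms
do. This linewidth matters: it controls how fast the phase of burst
content decorrelates across Welch sub-windows, and hence the variance of
both coupling estimators.

**Bursts.** Burst onsets follow a homogeneous Poisson process
(`burst_rate`, default 0.5 /s); durations are truncated-normal
(mean 300 ms, SD 100 ms, truncated at 120 ms by resampling); overlapping
draws are merged. The STN beta envelope is 1 outside bursts and
`burst_gain` (default 4) inside, with 20 ms Hann ramps so the injected
envelope has no single-sample steps. Ground truth records the merged
intervals in raw sample coordinates.

**Coupling.** The cortical beta component is built from a complex phasor
mixture: with weight c = `coupling_strength` inside the coupling region
(bursts only / everywhere / nowhere, per `coupling_mode`), the cortical
phasor is c·e^{i(φ_STN + lag)} + (1−c)·e^{iφ_ind}, with φ_ind an
independent oscillator. Coupling therefore acts on phase, not by mixing
raw traces, so coherence and dwPLI targets can be controlled
independently of amplitude. The cortical envelope is flat (bursts are an
STN-side phenomenon in this model).

**Reproducibility.** All randomness flows from one `SeedSequence(seed)`
split into five named substreams (bursts, two phases, two noises); the
same config is bit-identical across runs.

**What the generator does not emulate.** Line noise, movement and
electrode artifacts, non-stationary burst statistics, cortical bursts,
volume conduction (beyond what zero-lag tonic coupling represents),
multi-contact spatial structure. Passing tests on synthetic cohorts
therefore validate the estimators and inference machinery, not robustness
to recording artifacts.

## Preprocessing

High-pass (1 Hz) then beta band-pass (13–30 Hz), both zero-phase
fourth-order Butterworth applied forward–backward (`sosfiltfilt`), so the
effective attenuation is doubled and group delay is zero. Butterworth is
the conventional choice where only "fourth-order IIR" is fixed; its
monotone passband avoids ripple-induced envelope artifacts. The first
60 s of the raw timeline are discarded once per recording (operating-room
settling); 2 s are trimmed from each end of every filtered signal
(filter edge transients). Trim arithmetic uses floor(seconds × fs)
samples. All downstream sample indices are relative to the trimmed
origin. Note the 13/30 Hz band edges are −3 dB points per pass: ~3% of
broadband energy remains in the transition skirts (10–13 and 30–36 Hz);
outside a [10, 36] Hz guard band attenuation leaves < 1%.

For synthetic cohorts the head discard is set to 0 s: the generator is
stationary from the first sample, so the settling discard would only
shrink the data. Edge trims are kept.

## Burst detection

The envelope is |analytic signal| of the beta-band STN trace, smoothed by
a centered moving mean of round(50 ms × fs) samples with shrinking
windows at the edges (mirroring the common smoothing-call default).
Thresholds are linear-interpolation percentiles of the full trimmed
envelope, per contact: bursts are maximal runs strictly above the 75th
percentile, non-bursts strictly below the 50th; samples between are
transitional and unlabeled, keeping non-burst epochs away from burst
boundaries. Runs shorter than 100 ms are discarded. A constant envelope
produces equal thresholds and no epochs (documented, not an error).
Contacts with zero bursts are excluded from burst analyses; contacts with
one burst are additionally excluded from burst-adjacent analyses.

## Coupling estimators

Welch parameters are not dictated by the study design, so they are fixed
here as: sub-window length min(256, shortest usable segment) samples
(segments under 64 samples are unusable), Hamming taper, 50% overlap,
mean removal per sub-window (signals are already band-passed, so no
higher-order detrending). Sub-windows are pooled **across** segments of a
condition before forming either estimator — each epoch is treated as an
independent realization, and pooling is what gives short bursts ≥ 2
sub-windows. Same-condition segments are *not* concatenated: concatenation
would create phase discontinuities at the joins.

Coherence and dwPLI are computed from the same pooled sub-window spectra.
dwPLI follows the debiased-square estimator built on the imaginary
cross-spectrum; it is insensitive to zero-lag coupling, may be slightly
negative under the null (the debiasing), and is reported unclipped so its
null distribution is preserved. A vanished denominator (no imaginary
signal, e.g. exactly zero-lag coupling) is defined as 0 and flagged; the
vanishing test is relative to the cross-spectral magnitude so that float
round-off in constructed zero-lag cases is caught.

Band averages use the frequency-grid indices with 13 ≤ f ≤ 30 Hz on the
rFFT grid of the chosen window, fixed once per contact pair (the grid is
determined by the window length, itself set by the pair's segment
lengths) and reused verbatim for burst, non-burst and surrogate
estimates. Non-burst segments are capped at 100 per pair by uniform
subsampling without replacement (keeping temporal order), drawn from a
deterministic per-pair substream.

## Surrogate testing

Null hypothesis: observed coupling reflects only shared spectral content
and finite samples. Each of 200 surrogates rotates the STN beta signal by
a uniform 0.5–5 s offset (rounded to samples) and recomputes the
band-averaged coupling with identical Welch settings, band indices and
non-burst subsample. The empirical p-value is the fraction of surrogate
values ≥ observed (k/n; p = 0 is possible and reported as "< 1/200" in
summaries). Per-test RNG substreams are keyed on (seed, pair, condition,
metric), independent of execution order; the default seed is 1.

Epoch boundaries follow the STN signal under the rotation — equivalent to
re-detecting bursts on the rotated signal, since the amplitude envelope
and its percentiles are rotation-invariant; operationally the cortical
extraction windows are displaced by the shift while STN segments keep
their envelope-defined content. This choice is load-bearing for
calibration: non-burst epochs are *selected* for low STN amplitude, and
if the boundaries were instead frozen in cortical time, rotation would
sweep high-amplitude bursts into those windows; the |Im|-weighting of the
weighted phase-lag index then inflates the null variance and the
empirical p-values of truly uncoupled pairs pile up in the middle of the
unit interval (measured KS distance from uniform ≈ 0.18 on 500 uncoupled
pairs, versus ≈ 0.04 with epochs following the signal). The implemented
scheme keeps the observed statistic exchangeable with its surrogates; the
measured type-I error at α = 0.05 is 0.04–0.07 for both metrics.

Rotation preserves the marginal periodogram exactly. Welch *estimates* of
the rotated signal additionally re-draw the estimator's segmentation
noise (mean band-power deviation under 1%, individual shifts up to ~2%);
this is estimator variance, not a property of the surrogate.

The significance threshold for "exceeds surrogate expectations" in
contact summaries is p < 0.05, uncorrected (a config knob); per-pair
surrogate p-values are reported without multiplicity adjustment.

## Burst-adjacent and peri-burst analyses

**Adjacent triplets.** For each burst of length L: pre = last L samples
of the nearest earlier non-burst interval at least L samples long, post =
first L samples of the nearest later such interval. Too-short non-burst
runs are passed over, not shortened — durations stay exactly matched;
a burst with no qualifying interval on a side yields an invalid, counted
triplet. (Requiring the *immediately* adjacent run to be long enough
would invalidate most triplets structurally: the top quartile of samples
concentrates in few long burst runs while the bottom half splits into
many short non-burst runs.) Coupling is pooled per role across valid
triplets with a shared window and band grid.

**Peri-burst traces.** Offsets −50…+50 ms in 5 ms steps; at each offset a
15 ms window centered on (onset + offset) is cut from every burst with
full context inside the recording (others dropped and counted). A 15 ms
window cannot hold Welch sub-windows, so each window contributes one
Hamming-tapered DFT, zero-padded to 256 points so beta-band bins exist on
the grid, and the across-burst collection forms the trial dimension.
Bursts shorter than the positive span are retained; the window content is
whatever the signal holds at that offset. The baseline is the mean ± SD
over 20 independent draws of matched non-burst window sets (same count
and length, ≥ 50 ms from any burst).

## Statistics

Paired burst/non-burst contrasts: two-sided Wilcoxon signed-rank
(zero differences dropped; exact distribution for ≤ 25 non-zero pairs,
normal approximation with tie correction above) plus the paired t-test,
and the difference-standardized effect size d_z = mean(diff)/sd(diff)
(sample SD, n−1). The literature sometimes labels this paired Cohen's d;
outputs say `cohens_dz` to pin the variant. Spearman correlations use
average ranks with the t-approximation p. All-zero difference vectors and
constant inputs yield flagged/NaN results rather than exceptions deep in
the pipeline. The report flags contrasts that are statistically
significant but tiny (|d_z| < 0.3) rather than suppressing them.

## Problem sizes

Synthetic cohorts use 30 s recordings (500 pairs) for null calibration —
enough for ~10–15 bursts and ~50 non-burst runs per pair — and 60 s
recordings (100 pairs) for dissociation recovery, where the
burst-adjacent contrast needs a median of ~17 valid triplets per pair for
stable per-pair dwPLI estimates. The demo pipeline run uses the 120 s
generator default with the full 60 s head discard.

## Known limitations

* The EDF codec writes plain EDF (16-bit, 1 s records, equal rates); it
  is cross-checked against an independent reader in the tests but does
  not implement EDF+ annotations or variable rates.
* Welch settings are package conventions (see above); absolute coupling
  values depend on them, though burst/non-burst contrasts and surrogate
  comparisons share all settings by construction.
* dwPLI from few pooled sub-windows is noisy and can reach large negative
  values on null data; per-pair values from < ~10 sub-windows should be
  interpreted through their surrogate distribution, not their magnitude.
* The peri-burst estimator (single 15 ms DFT per burst) has coarse
  spectral resolution; its traces are meaningful relative to their
  matched baseline, not as absolute coherence.
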