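# Methods

This note documents the models, estimators, parameter choices and known
limitations of `thetalink`. It is written for a reader who wants to know
exactly what each stage computes and why, and what the synthetic cohorts do
and do not establish about real recordings.

## The synthetic cohort model

The generator stands in for in-vivo recordings of four regions (PrL, IL,
vHPC, dHPC) during free exploration. It is built so that every quantity the
analysis estimates has a known ground truth.

**Theta carrier.** Each hippocampal region carries an independent theta
oscillator constructed cycle by cycle: cycle frequencies are drawn uniformly
from 8 ± 1 Hz (the rodent theta peak with realistic cycle-to-cycle jitter),
and the instantaneous phase is piecewise linear through the cycle boundaries.

**Phase coupling.** Each prefrontal region follows one hippocampal driver —
by default PrL follows vHPC and IL follows dHPC, the preferential-circuit
structure the analysis is designed to detect. Within every driver cycle the
follower's phase lags the driver's by a fresh von Mises(μ, κ) draw, held
constant across the cycle (a phase-resetting construction). This makes κ the
single ground-truth synchrony knob: κ → ∞ gives a delta-like phase-lag
distribution, κ = 0 gives independent phases. The lag is deliberately *not*
smoothed between cycles: interpolating independent draws would drag the lag
through intermediate values and concentrate the marginal around its mean,
destroying the κ = 0 uniform limit. The cost is a small phase discontinuity
at cycle boundaries, which the theta band-pass smears over a few
milliseconds.

The two cross circuits (dHPC–PrL, vHPC–IL) are not explicitly coupled: their
phase difference is the slowly drifting relative phase of two independent
oscillators. Pooled over many trials this is uniform (width ≈ 2π), but within
a single short trial the drift dwells near whatever offset it currently has,
so *per-trial* cross-circuit histograms are lumpy and their widths are
wide-ranging. This matters only at strongly reduced trial durations; at the
default 10-minute trials the relative phase wraps many times per trial.

**Amplitude envelopes.** Theta envelopes are piecewise log-normal over 2.5-s
windows (median 60 µV, log-sd 0.5), linearly interpolated between window
midpoints. Pairwise envelope correlation is imposed on the latent Gaussians;
because the exponential transform shrinks correlations, the latent
correlation is found by numerically inverting
corr(e^{σz₁}, e^{σz₂}) = (e^{ρσ²} − 1)/(e^{σ²} − 1). The generator's
`envelope_rho` is therefore the *envelope-scale* Pearson correlation, which
is what the theta power-correlation analysis estimates.

**Noise and artifacts.** Regional background is Gaussian 1/f^β noise
(default β = 1.5, RMS 20 µV) synthesised by spectral shaping. Channels in a
bundle (4 per mPFC region, 6 per hippocampal region) share the regional
signal plus independent 1/f channel noise (RMS 8 µV); with probability
`bad_channel_prob` a channel is replaced by pure noise at signal-level RMS,
emulating an ungrounded electrode. All channels receive 60 Hz line
interference plus six harmonics (amplitude 5/k µV at harmonic k, common
phase per trial).

**Tracking.** Ground-truth speed follows an Ornstein–Uhlenbeck process
(mean 10 cm/s, stationary SD 5 cm/s, relaxation time 10 s) reflected at
zero, with a drifting heading, integrated and folded into the 46-cm arena,
sampled at 30 Hz. The OU parameters put substantial dwell time in each of
the < 5, 5–15 and > 15 cm/s regimes over a 10-minute session, and the
10-s relaxation time keeps in-band runs long relative to the 1-s smoothing
kernel, which is what makes velocity-gate recall testable. True speed is
retained as generator-only ground truth.

**Cohort template.** The default layout is 5 females and 4 males with trial
counts (25, 28, 23, 26, 28, 27, 27, 27, 25) — 236 sessions — and per-female
estrous stage multiplicities summing to each female's count. The stage
sequence round-robins through diestrus/proestrus/estrus/metestrus until the
multiplicities are exhausted. Effect sizes for sex or estrous differences
are *free parameters* (`group_coupling` overrides); the default cohort is
null in that respect.

**What the generator does not emulate.** No spikes or spike-field content,
no behavioral events, no non-stationary line noise, no electrode drift or
movement artifacts, no volume conduction, and phase coupling that is
constant within a session. Passing tests on synthetic cohorts therefore
demonstrate that the estimators recover the statistical structure they are
designed for — not that real recordings satisfy that structure.

## Preprocessing

* High-pass: 3rd-order Butterworth at 0.5 Hz, applied forward–backward.
  Two-pass (zero-phase) filtering is non-negotiable here because the
  phase-lag analysis interprets absolute phase differences.
* Line noise: fixed IIR notches (Q = 35) at 60, 120, …, 420 Hz, two-pass.
  A fixed notch is appropriate for the stationary synthetic interference;
  adaptive line filtering would be preferable for drifting real-world mains.
* Down-sampling: 8th-order low-pass at 800 Hz, then every (fs/2000)-th
  sample. The default generator rate is already 2 kHz; 32 kHz input
  exercises the decimation path.
* Two-pass filtering uses reflect-padding of 3 s (cleaning) / 1.5 s (theta
  band-pass): scipy's default pad length is far shorter than these filters'
  ring-down and leaves measurable edge transients, which matter because the
  theta-power gate thresholds on a *trial-mean* power.
* Channel QC: pairwise PLV via multitaper (2-s windows, NW = 3, 5 Slepian
  tapers, 0.5 Hz grid), averaged over 0.5–100 Hz. Exclusion is iterative:
  while any channel's mean PLV against the other kept channels is below 0.6,
  the worst channel is dropped and means recomputed. A single-pass rule
  would let one dead channel drag its good neighbours' means below
  threshold. Channels with RMS below 25% of the region median, or manually
  flagged, are dropped first. A region losing all channels is a hard error.
  QC is idempotent: rerunning on the kept set changes nothing.
* Velocity: XY tracking is linearly interpolated (edge-hold) from 30 Hz to
  the LFP timeline, converted to cm, differenced, and the speed magnitude
  smoothed with a Gaussian of SD 1 s (FFT convolution with edge-value
  padding). Gating keeps maximal runs with 5 ≤ v ≤ 15 cm/s lasting at least
  0.5 s — the minimum that fits a 0.4-s spectral window comfortably — using
  0-based half-open [start, end) indices throughout.
* Concatenation takes identical sample indices from all four regions, so
  cross-region alignment is exact by construction, and records every epoch
  join so spectral windows never straddle one.

## Spectral estimation

Welch PSD: 0.4-s Hamming windows, 90% overlap, 4000-point FFT (0.5 Hz grid
at 2 kHz), constant detrend per window, optional dB transform. Coherence:
2-s Hann windows, 50% overlap, cross- and auto-spectra averaged over windows
*before* normalising to |S_ab|²/(S_aa·S_bb). On concatenated series both
estimators run per segment and average weighted by window count. Fewer than
8 coherence windows flags the result low-confidence. Curve statistics are
clipped to 0.5–100 Hz; conventional bands are delta 1–4, theta 4–12, beta
15–30 and gamma 30–80 Hz.

## Theta coupling measures

**Power correlations.** Theta power over time is computed on full trials
(all velocities) in non-overlapping 2.5-s windows by multitaper (NW = 2.5,
4 tapers) on a 2048-point FFT grid, summed over 4–12 Hz. Because the window
(5000 samples) exceeds the FFT length, the windowed data are wrapped modulo
2048 before transforming — exactly the DFT of the full window subsampled to
the 2048-point grid (MATLAB's behaviour for this parameter combination), so
the grid step is ≈ 0.977 Hz. Per circuit and trial, the Pearson r across
windows is reported with r² and the two-tailed t-test p. Both r and r² are
emitted; group comparisons default to r².

**Phase lags.** Traces are theta-filtered (4th-order Butterworth 4–12 Hz,
two-pass; order 4 is stable under two-pass filtering at 2 kHz), Hilbert
phases subtracted, differences wrapped to (−π, π] (−π maps to +π), and
histogrammed in 200 bins of width π/100. Only samples where dHPC theta
power — analytic-signal magnitude squared, smoothed by a 0.5-s moving
average so within-cycle ripple does not toggle the gate — exceeds its trial
mean are counted.

**Width at half max.** The synchrony statistic counts every bin whose count
is ≥ half the modal count (ties inclusive) and multiplies by π/100. The
count-of-bins reading, rather than a contiguous peak width, is what allows
near-2π values for flat distributions; a delta distribution gives π/100.
Group statistics aggregate per-trial widths by subject; the "combined"
product pools all trials' histograms first and takes one width.

## Inference

**Hierarchical bootstrap.** Each replicate resamples subjects with
replacement, then each drawn subject's trials with replacement (same count),
and records the mean of subject means — equal subject weighting, so the
estimand is the subject-population mean even with unbalanced trial counts.
Default 10⁴ replicates, reducible for speed. Two groups are compared by
`p_boot = Pr(B ≥ A)` over the full cross product of replicate pairs,
computed by a rank trick (the bin-width → 0 limit of a joint-probability
matrix), then `p = 2·min(p_boot, 1 − p_boot)`. The calibration suite shows
this test's type-I error on nested null cohorts of the study's layout lies
roughly in the 5–10% band at α = 0.05 — the hierarchical bootstrap is
approximate, and the wide acceptance band reflects that.

**Functional tests.** Curves (one per subject, shared frequency grid) are
compared by the frequency-averaged pointwise between/within variance ratio,
calibrated by permuting subject labels (add-one p-value). The two-sample
test is the k = 2 case of the k-group version. The statistic is
self-normalising via its permutation null; no reference F distribution is
assumed.

**Circuit omnibus.** Subject-by-circuit means go through a Shapiro–Wilk
screen on the two-way residuals (α = .05): normal data get a
repeated-measures one-way ANOVA with Tukey HSD post hoc (studentized range
on the RM error term); otherwise Friedman with Dunn's rank post hoc
(Bonferroni over the 6 pairs). Exactly additive data (zero residuals) are
handled as a degenerate case without the screen.

**Alpha policy.** 0.05 for two-group comparisons; 0.0167 for estrous-stage
pairwise comparisons (three pairwise tests). Metestrus trials are dropped
from estrous comparisons (too few per subject to resample meaningfully).

## Pipeline

`run(RunConfig)` composes the stages deterministically: all stage seeds
derive from one root seed via seed-sequence spawning, and the config hash
(SHA-256 over all analysis-relevant parameters, output paths excluded)
identifies a run. Trials are processed one subject at a time so memory stays
bounded by a single subject's recordings. Per-estrous spectral curves
concatenate only that stage's trials for each female. Stages that cannot
produce a product for a particular stratum (e.g. no gated epoch long enough
for a coherence window in one stage of one subject) log a warning and omit
that stratum; genuine failures abort with a stage-named error.

## Problem sizes in the test and acceptance suites

Full-scale operation is 10-minute trials at 2 kHz (the generator also
produces 32 kHz for the decimation path). The verification suites scale
down where the property under test permits: signal-level checks
(coupling-width regimes, parameter recovery, velocity gating) use full
10-minute pairs; the end-to-end structural check runs the complete
236-trial cohort layout with 30-s trials, which preserves every structural
property (counts, strata, determinism, tight-vs-loose pooled width
ordering) at a fraction of the compute; bootstrap calibration operates on
trial-level scalar cohorts with subject random effects (mean 3 rad,
subject SD 0.4, trial SD 0.8 — the scale of per-trial phase-lag widths),
since the bootstrap consumes per-trial scalars and waveform synthesis adds
nothing to that question.

## Known limitations

* The fixed-notch line filter assumes stationary mains frequency.
* "Upsampled with padding" tracking is implemented as linear interpolation
  with edge hold; zero-order hold would also satisfy the constant-speed
  contract and differs only at the camera frame scale.
* The width statistic is resolution-coupled: its floor is one bin (π/100)
  and it is not debiased for sample count, so comparisons should hold the
  gated sample count roughly comparable across groups (the dHPC power gate
  keeps ≈ half of each trial, which does that in practice).
* Per-trial widths of *uncoupled* circuits are only near 2π when the trial
  is long enough for the relative phase to wrap repeatedly (see above).
* The hierarchical bootstrap's type-I error is approximate at small subject
  counts; p-values near α should be read accordingly.
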