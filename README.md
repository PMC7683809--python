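# thetalink

Analysis of theta-band (4–12 Hz) communication between hippocampal and
prefrontal subregions from multi-channel local field potentials (LFPs), for
electrophysiologists studying circuit-level synchrony in freely moving
rodents.

The package covers the full workflow for four simultaneously recorded
regions — prelimbic (PrL) and infralimbic (IL) medial prefrontal cortex and
ventral/dorsal hippocampal CA1 (vHPC, dHPC) — across multi-trial,
multi-subject cohorts with sex and estrous-stage group structure:

* **Synthetic cohorts** (`thetalink.synthetic`) — coupled theta oscillators
  with a per-cycle von Mises phase-lag model (concentration κ is the
  ground-truth synchrony knob), correlated log-normal amplitude envelopes,
  1/f background, 60 Hz line interference and harmonics, per-region channel
  bundles with optional outlier channels, and Ornstein–Uhlenbeck head-speed
  tracking. A built-in template reproduces the study layout: 5 female + 4
  male subjects, 23–28 trials each (236 total), with per-female estrous
  schedules.
* **Preprocessing** (`thetalink.preprocess`) — zero-phase 0.5 Hz high-pass,
  line-noise notches, down-sampling to 2 kHz, channel QC by multitaper
  phase-locking value (PLV < 0.6 excluded), regional mean LFP, movement
  velocity from 30 Hz tracking (Gaussian-smoothed, SD 1 s), and 5–15 cm/s
  velocity gating with epoch-aware concatenation.
* **Spectra** (`thetalink.spectral`) — Welch PSD (0.4 s window, 90% overlap,
  4000-point FFT) and magnitude-squared coherence (2 s Hann, 50% overlap)
  on gated concatenations, with frequency-band summaries.
* **Theta coupling** (`thetalink.theta_coupling`) — per-trial theta power
  correlations (multitaper power in 2.5 s windows, Pearson r/r²) and theta
  phase-lag distributions (Hilbert phase differences in 200 bins of π/100)
  gated by dHPC theta power, summarised by the **width at half max**: the
  number of histogram bins at or above half the modal count times the bin
  width, so reliable phase lags give widths near 0 and independent phases
  give widths near 2π.
* **Inference** (`thetalink.stats`) — hierarchical bootstrap (subjects, then
  trials, resampled with replacement; 10⁴ replicates), joint-probability
  comparison `p_boot = Pr(B ≥ A)` with two-tailed conversion
  `p = 2·min(p_boot, 1 − p_boot)`, permutation functional F tests for curve
  shapes, and within-subject circuit comparisons (RM-ANOVA + Tukey, or
  Friedman + Dunn when residuals fail a normality screen).
* **Pipeline** (`thetalink.pipeline`, CLI `thetalink`) — a deterministic,
  seeded end-to-end run emitting tidy CSV tables.

## Worked example

Simulate a tightly coupled and an uncoupled region pair and measure their
phase-lag synchrony and coherence:

```python
import numpy as np
from thetalink import (CouplingSpec, simulate_region_pair, theta_filter,
                       phase_lag_distribution, width_at_half_max,
                       coherence, band_mean, BANDS)

fs = 2000.0
tight = CouplingSpec(("vHPC", "PrL"), phase_lag_mean=0.4, phase_kappa=50.0,
                     envelope_rho=0.6)
loose = CouplingSpec(("vHPC", "IL"), phase_kappa=0.0)
for name, spec in [("vHPC-PrL (kappa=50)", tight), ("vHPC-IL  (kappa=0) ", loose)]:
    a, b = simulate_region_pair(600.0, fs, 8.0, spec, seed=1)
    d = phase_lag_distribution(theta_filter(a, fs), theta_filter(b, fs), fs,
                               prefiltered=True)
    c = coherence(a, b, fs)
    print(f"{name}: width at half max = {width_at_half_max(d):.4f} rad, "
          f"theta coherence = {band_mean(c, BANDS['theta']):.3f}")
```

```
vHPC-PrL (kappa=50): width at half max = 0.2827 rad, theta coherence = 0.649
vHPC-IL  (kappa=0) : width at half max = 6.2832 rad, theta coherence = 0.002
```

The tightly locked pair concentrates its phase differences in a few bins
(width ≪ 1 rad) and is coherent in the theta band; the uncoupled pair's
phase-difference histogram is flat (width = 2π ≈ 6.283 rad) with coherence
at the estimator floor.

Group inference on nested per-trial values (here a 2-rad separation in
width between sexes, with subject-level random effects):

```python
from thetalink import GroupedValues, compare_grouped
from thetalink.synthetic import simulate_scalar_cohort

f_vals = simulate_scalar_cohort({"F1": 25, "F2": 28, "F3": 23, "F4": 26,
                                 "F5": 28}, mean=5.0, seed=3)
m_vals = simulate_scalar_cohort({"M1": 27, "M2": 27, "M3": 27, "M4": 25},
                                mean=3.0, seed=4)
cmp_ = compare_grouped(GroupedValues("F", f_vals), GroupedValues("M", m_vals),
                       n_boot=10_000, seed=7)
print(f"females vs males: p_boot = {cmp_.p_boot:.5f}, "
      f"two-tailed p = {cmp_.p_two:.5f}")
```

```
females vs males: p_boot = 0.00000, two-tailed p = 0.00000
```

With a 2-rad separation no male bootstrap replicate exceeds any female
replicate, so the joint probability and its two-tailed conversion both hit
the resolution floor of 10⁴ replicates.

## Command line

```bash
thetalink simulate --config cohort.yaml --out raw/ --seed 3   # HDF5 + manifest
thetalink preprocess --in raw/ --out pre/                     # regional LFPs
thetalink run --in raw/ --out results/ --seed 3               # full analysis
```

Omitting `--config` uses the 9-subject, 236-trial study template.

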