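"""Circuit-level theta coupling measures.

Two per-trial measures of hippocampal–prefrontal theta (4–12 Hz)
communication:

* **Theta power correlations** — theta band power over time from the full
  trial (multitaper spectrogram, non-overlapping 2.5 s windows, NW = 2.5,
  2048-point FFT grid), then the Pearson correlation of the two regions'
  power time series.
* **Theta phase-lag distributions** — instantaneous phase from the analytic
  signal of the zero-phase theta-filtered traces, phase differences wrapped
  to (-pi, pi], histogrammed in 200 bins of width pi/100, restricted to
  samples where dorsal-hippocampal theta power exceeds its trial mean. The
  synchrony statistic is the width at half max: the number of bins whose
  count reaches half the modal count, times the bin width, so a reliable
  phase lag gives a narrow width and independent phases give a width near
  2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .preprocess import RegionalLFPSet

__all__ = [
    "PHASE_BIN_EDGES",
    "ThetaPowerSeries",
    "PowerCorrelation",
    "PhaseLagDistribution",
    "theta_power_series",
    "power_correlation",
    "theta_filter",
    "dhpc_power_gate",
    "phase_lag_distribution",
    "width_at_half_max",
]

THETA_LO, THETA_HI = 4.0, 12.0
#: Phase-difference histogram bins: -pi to pi in increments of pi/100.
PHASE_BIN_EDGES = np.linspace(-np.pi, np.pi, 201)
PHASE_BIN_WIDTH = np.pi / 100.0


@dataclass
class ThetaPowerSeries:
    """Per-region theta band power per non-overlapping window."""

    window_s: float
    power: dict[str, np.ndarray]
    trial_id: str = ""

    def __post_init__(self):
        lengths = {len(v) for v in self.power.values()}
        if len(lengths) > 1:
            raise ValueError("all regions must share window count")
        for r, p in self.power.items():
            if np.any(p < 0):
                raise ValueError(f"negative power in region {r}")

    @property
    def n_windows(self) -> int:
        return len(next(iter(self.power.values())))


@dataclass
class PowerCorrelation:
    trial_id: str
    region_pair: tuple[str, str]
    r: float
    r2: float
    p: float


@dataclass
class PhaseLagDistribution:
    """Binned theta phase-difference histogram with its width statistic."""

    counts: np.ndarray
    n_samples: int
    region_pair: tuple[str, str] = ("", "")
    trial_id: str = ""
    bin_edges: np.ndarray = None

    def __post_init__(self):
        if self.bin_edges is None:
            self.bin_edges = PHASE_BIN_EDGES
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one entry per bin")
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("counts must sum to n_samples")

    @property
    def width_hm(self) -> float:
        return width_at_half_max(self)


# --------------------------------------------------------------------------
# theta power over time
# --------------------------------------------------------------------------

def _wrapped_dft(x: np.ndarray, nfft: int) -> np.ndarray:
    """DFT of x subsampled to the nfft grid via modulo-nfft data wrapping.

    For a window longer than nfft this equals the DFT of the full window
    evaluated at frequencies k*fs/nfft (MATLAB's datawrap behaviour).
    x has shape (..., n).
    """
    n = x.shape[-1]
    if n <= nfft:
        return np.fft.rfft(x, n=nfft, axis=-1)
    pad = (-n) % nfft
    if pad:
        x = np.concatenate([x, np.zeros((*x.shape[:-1], pad))], axis=-1)
    folded = x.reshape(*x.shape[:-1], -1, nfft).sum(axis=-2)
    return np.fft.rfft(folded, axis=-1)


def _multitaper_band_power(x: np.ndarray, fs: float, nw: float, n_tapers: int,
                           nfft: int, lo: float, hi: float) -> np.ndarray:
    """Theta band power per window; x is (windows x samples)."""
    n = x.shape[-1]
    tapers = signal.windows.dpss(n, nw, n_tapers)
    spec = _wrapped_dft(x[:, None, :] * tapers[None, :, :], nfft)
    psd = (np.abs(spec) ** 2) / fs
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    return psd[..., band].sum(axis=-1).mean(axis=-1)


def theta_power_series(regional_set: RegionalLFPSet, window_s: float = 2.5,
                       nw: float = 2.5, n_tapers: int = 4,
                       nfft: int = 2048) -> ThetaPowerSeries:
    """Theta band power over time for every region of a full trial.

    Uses non-overlapping ``window_s`` windows regardless of running velocity;
    per window, the multitaper spectrum summed over 4–12 Hz.
    """
    n_win_samp = int(round(window_s * regional_set.fs))
    n_win = regional_set.n_samples // n_win_samp
    if n_win < 1:
        raise ValueError("trial shorter than one power window")
    power = {}
    for region, trace in regional_set.traces.items():
        x = trace[: n_win * n_win_samp].reshape(n_win, n_win_samp)
        power[region] = _multitaper_band_power(x, regional_set.fs, nw, n_tapers,
                                               nfft, THETA_LO, THETA_HI)
    return ThetaPowerSeries(window_s=window_s, power=power,
                            trial_id=regional_set.trial_id)


def power_correlation(series_a: np.ndarray, series_b: np.ndarray,
                      region_pair: tuple[str, str] = ("", ""),
                      trial_id: str = "") -> PowerCorrelation:
    """Pearson correlation of two theta power time series with two-tailed p."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    if len(a) < 10:
        raise ValueError("need >= 10 windows for a power correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance power series: correlation undefined")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return PowerCorrelation(trial_id=trial_id, region_pair=region_pair,
                            r=r, r2=r * r, p=float(res.pvalue))


# --------------------------------------------------------------------------
# theta phase lags
# --------------------------------------------------------------------------

def theta_filter(trace: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase theta band-pass: 4th-order Butterworth 4–12 Hz, two-pass."""
    if fs < 100:
        raise ValueError("sampling rate too low for the theta band-pass")
    sos = signal.butter(4, [THETA_LO, THETA_HI], btype="bandpass", fs=fs,
                        output="sos")
    trace = np.asarray(trace, dtype=np.float64)
    # generous reflect-padding: the default is far shorter than the filter's
    # ring-down at these corner frequencies and leaves edge transients
    padlen = min(len(trace) - 1, int(round(1.5 * fs)))
    return signal.sosfiltfilt(sos, trace, padlen=padlen)


def dhpc_power_gate(dhpc_trace: np.ndarray, fs: float,
                    smooth_s: float = 0.5) -> np.ndarray:
    """Mask of samples where dHPC theta power exceeds its trial mean.

    Instantaneous power is the squared magnitude of the analytic signal of
    the theta-filtered trace, smoothed with a ``smooth_s`` moving average so
    within-cycle ripple does not toggle the mask.
    """
    filt = theta_filter(dhpc_trace, fs)
    power = np.abs(signal.hilbert(filt)) ** 2
    w = max(1, int(round(smooth_s * fs)))
    if w > 1 and len(power) > w:
        kernel = np.full(w, 1.0 / w)
        padded = np.concatenate([np.full(w, power[0]), power, np.full(w, power[-1])])
        power = signal.fftconvolve(padded, kernel, mode="same")[w:-w]
    if not power.any():
        return np.zeros(len(power), dtype=bool)
    return power > power.mean()


def instantaneous_phase(theta_trace: np.ndarray) -> np.ndarray:
    """Analytic-signal phase angle in (-pi, pi] of a theta-filtered trace."""
    return np.angle(signal.hilbert(np.asarray(theta_trace, dtype=np.float64)))


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    out = np.mod(-np.asarray(dphi) + np.pi, 2 * np.pi)
    return np.pi - out


def phase_lag_distribution(trace_a: np.ndarray, trace_b: np.ndarray, fs: float,
                           gate_mask: np.ndarray | None = None,
                           region_pair: tuple[str, str] = ("", ""),
                           trial_id: str = "",
                           prefiltered: bool = False) -> PhaseLagDistribution:
    """Histogram of instantaneous theta phase differences phi_a - phi_b.

    Traces are theta-filtered (unless ``prefiltered``), Hilbert-transformed,
    and the wrapped phase difference of the gated samples is binned from -pi
    to pi in increments of pi/100.
    """
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    if not prefiltered:
        a = theta_filter(a, fs)
        b = theta_filter(b, fs)
    dphi = wrap_phase(instantaneous_phase(a) - instantaneous_phase(b))
    if gate_mask is not None:
        gate_mask = np.asarray(gate_mask, dtype=bool)
        if gate_mask.shape != dphi.shape:
            raise ValueError("gate mask must align with traces")
        dphi = dphi[gate_mask]
    if dphi.size == 0:
        raise ValueError("empty gate: no samples to histogram")
    counts, _ = np.histogram(dphi, bins=PHASE_BIN_EDGES)
    return PhaseLagDistribution(counts=counts, n_samples=int(counts.sum()),
                                region_pair=region_pair, trial_id=trial_id)


def width_at_half_max(dist: PhaseLagDistribution) -> float:
    """Width (radians) at half the maximum histogram peak.

    Counts every bin whose count is >= half the modal count (ties inclusive)
    and multiplies by the pi/100 bin width; a delta distribution gives
    pi/100, a flat one gives 2*pi.
    """
    if dist.n_samples <= 0:
        raise ValueError("empty distribution")
    half = dist.counts.max() / 2.0
    return float((dist.counts >= half).sum() * PHASE_BIN_WIDTH)


def pooled_distribution(dists: list[PhaseLagDistribution],
                        region_pair: tuple[str, str] = ("", "")) -> PhaseLagDistribution:
    """Pool trials' histograms into one combined distribution."""
    if not dists:
        raise ValueError("no distributions to pool")
    counts = np.sum([d.counts for d in dists], axis=0)
    return PhaseLagDistribution(counts=counts, n_samples=int(counts.sum()),
                                region_pair=region_pair, trial_id="pooled")
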