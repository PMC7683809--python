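"""Raw multi-channel LFP preprocessing.

Turns raw per-region channel bundles into velocity-annotated regional LFPs:

1. per-channel cleaning — 0.5 Hz high-pass, attenuation of 60 Hz line
   interference and its six harmonics, down-sampling to the 2 kHz analysis
   rate (all filtering is two-pass / zero-phase, which the downstream
   phase-lag analysis requires);
2. channel quality control — pairwise phase-locking values (PLV) over
   0.5–100 Hz via the multitaper method; a channel whose mean PLV against all
   others in its region falls below threshold (default 0.6) is an outlier and
   is dropped, as are pre-flagged or abnormally low-amplitude channels;
3. regional LFP — samplewise mean voltage of the kept channels;
4. movement velocity from 30 Hz XY tracking (upsampled to the LFP rate,
   converted to cm, speed smoothed with a Gaussian kernel of SD 1 s) and
   gating to 5–15 cm/s running epochs;
5. concatenation of gated epochs across a subject's trials into one long
   four-region series with recorded epoch boundaries, so spectral windows can
   avoid straddling joins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import TRACK_FS, TrialRecording

__all__ = [
    "ANALYSIS_FS",
    "ChannelQCReport",
    "RegionalLFPSet",
    "VelocityEpochs",
    "ConcatenatedSeries",
    "clean_channel",
    "plv_matrix",
    "channel_qc",
    "regional_lfp",
    "compute_velocity",
    "velocity_epochs",
    "concatenate_epochs",
    "preprocess_trial",
]

ANALYSIS_FS = 2000.0
LINE_FREQS = tuple(60.0 * k for k in range(1, 8))  # 60 Hz + six harmonics


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class ChannelQCReport:
    """Per-region channel QC outcome.

    ``plv_matrix`` is the channels x channels mean PLV over 0.5–100 Hz
    (symmetric, unit diagonal); ``kept_mask`` marks surviving channels.
    """

    region: str
    plv_matrix: np.ndarray
    kept_mask: np.ndarray
    threshold: float = 0.6

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


@dataclass
class RegionalLFPSet:
    """Cleaned per-region mean LFP at the analysis rate, with aligned velocity."""

    fs: float
    traces: dict[str, np.ndarray]
    velocity: np.ndarray
    subject_id: str = ""
    sex: str = ""
    estrous: str = "none"
    trial_id: str = ""
    qc: dict[str, ChannelQCReport] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all regional traces must share length")
        if len(self.velocity) != next(iter(lengths)):
            raise ValueError("velocity must align sample-for-sample with traces")

    @property
    def n_samples(self) -> int:
        return len(self.velocity)


@dataclass
class VelocityEpochs:
    """Half-open [start, end) sample index runs where lo <= v <= hi."""

    intervals: list[tuple[int, int]]
    lo: float = 5.0
    hi: float = 15.0

    def total_samples(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class ConcatenatedSeries:
    """Gated epochs joined into one long aligned four-region series.

    ``boundaries`` holds the cumulative sample offsets of epoch joins
    (excluding 0 and the total length) so windowed estimators can avoid
    windows that straddle a join.
    """

    fs: float
    traces: dict[str, np.ndarray]
    boundaries: list[int]
    subject_id: str = ""

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    def segments(self) -> list[tuple[int, int]]:
        edges = [0, *self.boundaries, self.n_samples]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


# --------------------------------------------------------------------------
# per-channel cleaning
# --------------------------------------------------------------------------

def _cleaning_sos(fs: float) -> np.ndarray:
    """High-pass (0.5 Hz, 3rd-order Butterworth) + notches at 60..420 Hz, Q=35."""
    sos = signal.butter(3, 0.5, btype="highpass", fs=fs, output="sos")
    for f0 in LINE_FREQS:
        if f0 < fs / 2:
            b, a = signal.iirnotch(f0, Q=35.0, fs=fs)
            sos = np.vstack([sos, signal.tf2sos(b, a)])
    return sos


def clean_channel(trace: np.ndarray, fs_in: float) -> np.ndarray:
    """Clean one raw channel and return it at the 2 kHz analysis rate.

    Removes DC/drift, attenuates 60 Hz interference and six harmonics
    (fixed IIR notches, appropriate for stationary line noise), then
    decimates to 2 kHz with an 800 Hz anti-alias low-pass when the input
    rate is higher. All filters run forward–backward (zero phase).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if fs_in < ANALYSIS_FS:
        raise ValueError(f"input rate {fs_in} Hz below analysis rate {ANALYSIS_FS} Hz")
    factor = fs_in / ANALYSIS_FS
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"input rate {fs_in} Hz not an integer multiple of 2 kHz")
    factor = int(round(factor))
    # long reflect-padding: the 0.5 Hz high-pass rings for seconds and the
    # default padlen leaves visible edge transients
    padlen = min(len(trace) - 1, int(round(3 * fs_in)))
    out = signal.sosfiltfilt(_cleaning_sos(fs_in), trace, padlen=padlen)
    if factor > 1:
        aa = signal.butter(8, 800.0, btype="lowpass", fs=fs_in, output="sos")
        out = signal.sosfiltfilt(aa, out)[::factor]
    return out


# --------------------------------------------------------------------------
# multitaper PLV channel QC
# --------------------------------------------------------------------------

def _tapered_ffts(channels: np.ndarray, fs: float, window_s: float, nw: float,
                  n_tapers: int) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper windowed FFTs: (channels x windows x tapers x freqs), freqs."""
    n_win_samp = int(round(window_s * fs))
    n_ch, n = channels.shape
    n_win = n // n_win_samp
    if n_win < 1:
        raise ValueError("trace shorter than one multitaper window")
    tapers = signal.windows.dpss(n_win_samp, nw, n_tapers)
    x = channels[:, : n_win * n_win_samp].reshape(n_ch, n_win, n_win_samp)
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n_win_samp, 1.0 / fs)
    return spec, freqs


def plv_matrix(channels: np.ndarray, fs: float, fmin: float = 0.5,
               fmax: float = 100.0, window_s: float = 2.0, nw: float = 3.0,
               n_tapers: int = 5) -> np.ndarray:
    """Pairwise phase-locking values averaged over [fmin, fmax].

    PLV at each frequency is the magnitude of the mean unit cross-phasor over
    windows and tapers; the returned matrix is its mean across the band
    (symmetric, unit diagonal).
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.ndim != 2 or channels.shape[0] < 2:
        raise ValueError("need a (channels x samples) array with >= 2 channels")
    spec, freqs = _tapered_ffts(channels, fs, window_s, nw, n_tapers)
    band = (freqs >= fmin) & (freqs <= fmax)
    u = spec[..., band]
    u = u / np.maximum(np.abs(u), 1e-30)  # unit phasors
    n_ch = channels.shape[0]
    out = np.eye(n_ch)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            plv_f = np.abs(np.mean(u[i] * np.conj(u[j]), axis=(0, 1)))
            out[i, j] = out[j, i] = float(np.mean(plv_f))
    return out


def channel_qc(channels_by_region: dict[str, np.ndarray], fs: float,
               threshold: float = 0.6,
               manual_flags: dict[str, np.ndarray] | None = None,
               rms_fraction: float = 0.25) -> dict[str, ChannelQCReport]:
    """Flag outlier channels per region by mean PLV against their neighbours.

    A channel is dropped when its mean off-diagonal PLV is below
    ``threshold``, when pre-flagged (poorly grounded), or when its RMS falls
    below ``rms_fraction`` of the region's median channel RMS (the
    low-amplitude rule). Raises if a region loses all channels.
    """
    manual_flags = manual_flags or {}
    reports: dict[str, ChannelQCReport] = {}
    for region, chans in channels_by_region.items():
        chans = np.asarray(chans, dtype=np.float64)
        if chans.shape[0] < 2:
            raise ValueError(f"region {region}: need >= 2 channels for QC")
        mat = plv_matrix(chans, fs)
        kept = np.ones(chans.shape[0], dtype=bool)
        rms = np.sqrt(np.mean(chans * chans, axis=1))
        kept &= rms >= rms_fraction * np.median(rms)
        flags = manual_flags.get(region)
        if flags is not None:
            kept &= ~np.asarray(flags, dtype=bool)
        # drop the worst outlier and re-average until every survivor locks to
        # its neighbours: a single bad channel must not drag the others' means
        # below threshold
        while kept.sum() >= 2:
            sub = mat[np.ix_(kept, kept)]
            off = (sub.sum(axis=1) - 1.0) / (kept.sum() - 1)
            if off.min() >= threshold:
                break
            worst = np.flatnonzero(kept)[int(np.argmin(off))]
            kept[worst] = False
        else:
            raise ValueError(f"channel QC excluded every channel in region {region}")
        if not kept.any():
            raise ValueError(f"channel QC excluded every channel in region {region}")
        reports[region] = ChannelQCReport(region=region, plv_matrix=mat,
                                          kept_mask=kept, threshold=threshold)
    return reports


def regional_lfp(channels: np.ndarray, kept_mask: np.ndarray) -> np.ndarray:
    """Samplewise mean voltage over the kept channels."""
    channels = np.asarray(channels, dtype=np.float64)
    kept_mask = np.asarray(kept_mask, dtype=bool)
    if kept_mask.shape[0] != channels.shape[0]:
        raise ValueError("mask length must equal channel count")
    if not kept_mask.any():
        raise ValueError("no channels kept")
    return channels[kept_mask].mean(axis=0)


# --------------------------------------------------------------------------
# velocity
# --------------------------------------------------------------------------

def _gaussian_smooth(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    """FFT-based Gaussian smoothing with edge-value padding (sigma can be large)."""
    half = int(math.ceil(4 * sigma_samples))
    k = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (k / sigma_samples) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return signal.fftconvolve(padded, kernel, mode="same")[half:-half]


def compute_velocity(tracking_xy: np.ndarray, fs_track: float, px_per_cm: float,
                     n_samples: int, fs_lfp: float = ANALYSIS_FS) -> np.ndarray:
    """Movement speed (cm/s) aligned sample-for-sample with the LFP.

    XY coordinates are linearly interpolated between camera frames with
    edge-value hold out to the LFP timeline, converted to cm, differentiated,
    and the speed magnitude smoothed with a Gaussian kernel of SD 1 s.
    """
    xy = np.asarray(tracking_xy, dtype=np.float64)
    if xy.ndim != 2 or xy.shape[0] != 2 or xy.shape[1] < 2:
        raise ValueError("tracking_xy must be (2 x frames) with >= 2 frames")
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be > 0")
    t_frames = np.arange(xy.shape[1]) / fs_track
    t_lfp = np.arange(n_samples) / fs_lfp
    x = np.interp(t_lfp, t_frames, xy[0]) / px_per_cm
    y = np.interp(t_lfp, t_frames, xy[1]) / px_per_cm
    speed = np.hypot(np.diff(x, prepend=x[0]), np.diff(y, prepend=y[0])) * fs_lfp
    return _gaussian_smooth(speed, 1.0 * fs_lfp)


def velocity_epochs(velocity: np.ndarray, lo: float = 5.0, hi: float = 15.0,
                    min_dur_s: float = 0.5, fs: float = ANALYSIS_FS) -> VelocityEpochs:
    """Maximal runs with lo <= v <= hi, discarding runs shorter than min_dur_s."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    ok = (velocity >= lo) & (velocity <= hi)
    edges = np.flatnonzero(np.diff(ok.astype(np.int8)))
    starts = [0] if ok[0] else []
    ends: list[int] = []
    for e in edges:
        if ok[e]:          # True -> False transition: run ends at e + 1
            ends.append(int(e) + 1)
        else:
            starts.append(int(e) + 1)
    if ok[-1]:
        ends.append(len(velocity))
    min_len = int(round(min_dur_s * fs))
    intervals = [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]
    return VelocityEpochs(intervals=intervals, lo=lo, hi=hi)


# --------------------------------------------------------------------------
# trial-level assembly
# --------------------------------------------------------------------------

def preprocess_trial(trial: TrialRecording, plv_threshold: float = 0.6,
                     manual_flags: dict[str, np.ndarray] | None = None) -> RegionalLFPSet:
    """Clean, QC and average one trial's channels; attach aligned velocity."""
    cleaned = {
        region: np.stack([clean_channel(ch, trial.fs) for ch in chans])
        for region, chans in trial.lfp.items()
    }
    reports = channel_qc(cleaned, ANALYSIS_FS, threshold=plv_threshold,
                         manual_flags=manual_flags)
    traces = {
        region: regional_lfp(cleaned[region], reports[region].kept_mask)
        for region in cleaned
    }
    n = len(next(iter(traces.values())))
    velocity = compute_velocity(trial.tracking_xy, TRACK_FS, trial.px_per_cm, n)
    return RegionalLFPSet(fs=ANALYSIS_FS, traces=traces, velocity=velocity,
                          subject_id=trial.subject_id, sex=trial.sex,
                          estrous=trial.estrous, trial_id=trial.trial_id,
                          qc=reports)


def concatenate_epochs(trials: list[RegionalLFPSet],
                       epochs_per_trial: list[VelocityEpochs]) -> ConcatenatedSeries:
    """Join each trial's gated epochs into one long aligned series.

    The same sample indices are taken from all four regions, so cross-region
    alignment is preserved; epoch joins are recorded in ``boundaries``.
    """
    if len(trials) != len(epochs_per_trial):
        raise ValueError("need one VelocityEpochs per trial")
    if not trials:
        raise ValueError("no trials to concatenate")
    fs = trials[0].fs
    region_set = set(trials[0].traces)
    for tr in trials:
        if tr.fs != fs:
            raise ValueError("all trials must share the sampling rate")
        if set(tr.traces) != region_set:
            raise ValueError("all trials must share the region set")
    pieces: dict[str, list[np.ndarray]] = {r: [] for r in region_set}
    boundaries: list[int] = []
    total = 0
    for tr, eps in zip(trials, epochs_per_trial):
        for s, e in eps.intervals:
            for r in region_set:
                pieces[r].append(tr.traces[r][s:e])
            total += e - s
            boundaries.append(total)
    if total == 0:
        raise ValueError("no gated samples to concatenate")
    boundaries = boundaries[:-1]  # last edge is the series end, not a join
    traces = {r: np.concatenate(pieces[r]) for r in region_set}
    return ConcatenatedSeries(fs=fs, traces=traces, boundaries=boundaries,
                              subject_id=trials[0].subject_id)
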