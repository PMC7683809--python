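"""PSD and coherence estimation on velocity-gated, concatenated LFP series.

Welch power spectral densities use a 0.4 s moving window with 90% overlap and
4000-point FFTs (0.5 Hz grid at the 2 kHz analysis rate), Hamming-tapered with
per-window constant detrend; plotted values are decibel-transformed.
Magnitude-squared coherence uses a 2 s Hann window with 50% overlap. When a
series was assembled by concatenating gated epochs, estimation runs per
segment and averages spectra (weighted by window count) so no window straddles
an epoch join. Curve statistics are clipped to 0.5–100 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BANDS",
    "BandDefinition",
    "SpectralResult",
    "welch_psd",
    "coherence",
    "band_mean",
]

DEFAULT_FREQ_RANGE = (0.5, 100.0)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError("band lo must be < hi")


#: Conventional rodent LFP frequency bands.
BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 12.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 80.0),
}


@dataclass
class SpectralResult:
    """A PSD or coherence curve on a frequency grid.

    ``values`` are µV²/Hz (or dB if ``db``) for kind "psd", or magnitude-
    squared coherence in [0, 1] for kind "coherence".
    """

    freqs: np.ndarray
    values: np.ndarray
    kind: str
    label: str = ""
    subject_id: str = ""
    sex: str = ""
    estrous: str = "none"
    db: bool = False
    low_confidence: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("psd", "coherence"):
            raise ValueError("kind must be 'psd' or 'coherence'")
        if len(self.freqs) != len(self.values):
            raise ValueError("freqs and values must align")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def _segments_or_whole(n: int, boundaries) -> list[tuple[int, int]]:
    edges = [0, *(boundaries or []), n]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _clip(freqs: np.ndarray, curves: list[np.ndarray], freq_range):
    if freq_range is None:
        return freqs, curves
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    return freqs[sel], [c[sel] for c in curves]


def _n_windows(seg_len: int, nperseg: int, step: int) -> int:
    if seg_len < nperseg:
        return 0
    return 1 + (seg_len - nperseg) // step


def welch_psd(trace: np.ndarray, fs: float, window_s: float = 0.4,
              overlap: float = 0.9, nfft: int = 4000, db: bool = True,
              boundaries=None, freq_range=DEFAULT_FREQ_RANGE) -> SpectralResult:
    """Welch PSD with Hamming taper and constant detrend per window.

    ``boundaries`` (sample offsets of concatenation joins) restricts windows
    to within segments; segment spectra are averaged weighted by window count.
    Pass ``freq_range=None`` for the full grid (e.g. for variance checks).
    """
    trace = np.asarray(trace, dtype=np.float64)
    nperseg = int(round(window_s * fs))
    if len(trace) < nperseg:
        raise ValueError("trace shorter than one Welch window")
    step = max(1, int(round(nperseg * (1 - overlap))))
    acc = None
    total_w = 0
    freqs = None
    for s, e in _segments_or_whole(len(trace), boundaries):
        w = _n_windows(e - s, nperseg, step)
        if w == 0:
            continue
        freqs, pxx = signal.welch(trace[s:e], fs=fs, window="hamming",
                                  nperseg=nperseg, noverlap=nperseg - step,
                                  nfft=nfft, detrend="constant")
        acc = pxx * w if acc is None else acc + pxx * w
        total_w += w
    if acc is None:
        raise ValueError("no segment long enough for a Welch window")
    pxx = acc / total_w
    freqs, (pxx,) = _clip(freqs, [pxx], freq_range)
    values = 10.0 * np.log10(np.maximum(pxx, np.finfo(float).tiny)) if db else pxx
    return SpectralResult(freqs=freqs, values=values, kind="psd", db=db,
                          meta={"window_s": window_s, "overlap": overlap,
                                "nfft": nfft, "n_windows": total_w})


def coherence(trace_a: np.ndarray, trace_b: np.ndarray, fs: float,
              window_s: float = 2.0, overlap: float = 0.5,
              boundaries=None, freq_range=DEFAULT_FREQ_RANGE) -> SpectralResult:
    """Magnitude-squared coherence |S_ab|^2 / (S_aa S_bb), Hann-tapered.

    Cross- and auto-spectra are averaged across windows (within segments, when
    ``boundaries`` is given) before normalising. Fewer than 8 windows total
    triggers a warning and flags the result low-confidence.
    """
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    nperseg = int(round(window_s * fs))
    nfft = nperseg
    step = max(1, int(round(nperseg * (1 - overlap))))
    s_ab = s_aa = s_bb = None
    total_w = 0
    freqs = None
    for s, e in _segments_or_whole(len(a), boundaries):
        w = _n_windows(e - s, nperseg, step)
        if w == 0:
            continue
        kw = dict(fs=fs, window="hann", nperseg=nperseg,
                  noverlap=nperseg - step, nfft=nfft, detrend="constant")
        freqs, pab = signal.csd(a[s:e], b[s:e], **kw)
        _, paa = signal.welch(a[s:e], **kw)
        _, pbb = signal.welch(b[s:e], **kw)
        if s_ab is None:
            s_ab, s_aa, s_bb = pab * w, paa * w, pbb * w
        else:
            s_ab += pab * w
            s_aa += paa * w
            s_bb += pbb * w
        total_w += w
    if s_ab is None:
        raise ValueError("no segment long enough for a coherence window")
    low_confidence = total_w < 8
    if low_confidence:
        warnings.warn(f"coherence estimated from only {total_w} windows; "
                      "variance will be high", stacklevel=2)
    denom = np.maximum(s_aa * s_bb, np.finfo(float).tiny)
    coh = np.abs(s_ab) ** 2 / denom
    freqs, (coh,) = _clip(freqs, [np.clip(coh, 0.0, 1.0)], freq_range)
    return SpectralResult(freqs=freqs, values=coh, kind="coherence",
                          low_confidence=low_confidence,
                          meta={"window_s": window_s, "overlap": overlap,
                                "n_windows": total_w})


def band_mean(result: SpectralResult, band: BandDefinition) -> float:
    """Mean of the curve over frequency bins in [band.lo, band.hi]."""
    sel = (result.freqs >= band.lo) & (result.freqs <= band.hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name} "
                         f"[{band.lo}, {band.hi}] Hz")
    return float(result.values[sel].mean())
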