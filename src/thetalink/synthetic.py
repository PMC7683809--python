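"""Synthetic multi-region LFP cohort generator.

Emulates simultaneous local field potential recordings from four rat brain
regions — prelimbic (PrL) and infralimbic (IL) medial prefrontal cortex and
ventral/dorsal hippocampal CA1 (vHPC, dHPC) — during free exploration of a
familiar arena, together with 30 Hz overhead XY head tracking and per-trial
metadata (subject, sex, estrous stage).

The generative model:

* Each hippocampal region carries an independent theta (4–12 Hz) oscillator
  built cycle by cycle, with per-cycle frequency jittered uniformly around the
  carrier (default 8 ± 1 Hz).
* Each prefrontal region is phase-coupled to one hippocampal driver: within
  every driver theta cycle the follower's phase lags the driver's by a fresh
  von Mises(mu, kappa) draw, so the concentration kappa is the single
  ground-truth knob controlling phase-lag reliability.
* Theta amplitude envelopes are piecewise (2.5 s windows) bivariate log-normal
  with the latent Gaussian correlation calibrated numerically so the envelope
  correlation matches the requested value.
* Additive 1/f^beta background noise, 60 Hz line interference plus six
  harmonics, per-region channel bundles sharing the regional signal with
  independent channel noise, and occasional outlier ("bad") channels that are
  pure noise.
* Head position follows an Ornstein–Uhlenbeck speed process (reflected at 0)
  with a slowly drifting heading, confined to the arena, so ground-truth
  running-speed epochs are known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "REGIONS",
    "MPFC_REGIONS",
    "HPC_REGIONS",
    "CIRCUITS",
    "ESTROUS_STAGES",
    "CouplingSpec",
    "CohortConfig",
    "TrialRecording",
    "default_coupling_specs",
    "table1_cohort_config",
    "simulate_region_pair",
    "simulate_trial",
    "simulate_cohort",
]

REGIONS = ("PrL", "IL", "vHPC", "dHPC")
MPFC_REGIONS = ("PrL", "IL")
HPC_REGIONS = ("vHPC", "dHPC")
#: The four hippocampal–prefrontal circuits under study, ordered (HPC, mPFC).
CIRCUITS = (("vHPC", "PrL"), ("dHPC", "PrL"), ("vHPC", "IL"), ("dHPC", "IL"))
ESTROUS_STAGES = ("diestrus", "proestrus", "estrus", "metestrus")

ARENA_CM = 46.0  # square arena side
TRACK_FS = 30.0  # overhead camera frame rate, Hz


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Pairwise theta coupling between two regions.

    Parameters
    ----------
    region_pair : tuple of str
        Ordered (driver, follower) region labels.
    phase_lag_mean : float
        Mean follower phase lag, radians in (-pi, pi].
    phase_kappa : float
        von Mises concentration of the per-cycle lag; 0 means the phases are
        independent, large values mean tight locking.
    envelope_rho : float
        Target Pearson correlation of the two theta amplitude envelopes,
        in [-1, 1].
    """

    region_pair: tuple[str, str]
    phase_lag_mean: float = 0.0
    phase_kappa: float = 0.0
    envelope_rho: float = 0.0

    def __post_init__(self):
        a, b = self.region_pair
        for r in (a, b):
            if r not in REGIONS:
                raise ValueError(f"unknown region label {r!r}; expected one of {REGIONS}")
        if not np.isfinite(self.phase_kappa) or self.phase_kappa < 0:
            raise ValueError(f"phase_kappa must be >= 0, got {self.phase_kappa}")
        if not -math.pi < self.phase_lag_mean <= math.pi:
            raise ValueError("phase_lag_mean must lie in (-pi, pi]")
        if abs(self.envelope_rho) > 1:
            raise ValueError(f"|envelope_rho| must be <= 1, got {self.envelope_rho}")


def default_coupling_specs() -> tuple[CouplingSpec, ...]:
    """Coupling template: tight vHPC–PrL and dHPC–IL, loose cross circuits.

    The tight/loose assignment mirrors the preferential-circuit structure the
    analysis is designed to detect; the numeric values are free generator
    parameters (the source study reports no effect sizes in physical units).
    """
    return (
        CouplingSpec(("vHPC", "PrL"), phase_lag_mean=0.5, phase_kappa=20.0, envelope_rho=0.6),
        CouplingSpec(("dHPC", "PrL"), phase_lag_mean=0.0, phase_kappa=0.0, envelope_rho=0.1),
        CouplingSpec(("vHPC", "IL"), phase_lag_mean=0.0, phase_kappa=0.0, envelope_rho=0.1),
        CouplingSpec(("dHPC", "IL"), phase_lag_mean=0.5, phase_kappa=20.0, envelope_rho=0.6),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Layout and signal parameters for a simulated cohort.

    ``subjects`` is a list of ``(subject_id, sex)`` with sex in {"F", "M"}.
    ``trials_per_subject`` is either one integer for all subjects or a
    per-subject list. ``estrous_schedule`` maps female subject ids to
    per-trial stage labels; males must not appear in it.
    ``coupling`` holds the cohort-wide circuit specs; ``group_coupling``
    optionally overrides them per sex ({"M": (...), "F": (...)}).
    """

    subjects: tuple[tuple[str, str], ...]
    trials_per_subject: int | tuple[int, ...] = 25
    estrous_schedule: dict[str, tuple[str, ...]] = field(default_factory=dict)
    coupling: tuple[CouplingSpec, ...] = field(default_factory=default_coupling_specs)
    group_coupling: dict[str, tuple[CouplingSpec, ...]] = field(default_factory=dict)
    fs_raw: float = 2000.0
    duration_s: float = 600.0
    n_channels: dict[str, int] = field(
        default_factory=lambda: {"PrL": 4, "IL": 4, "vHPC": 6, "dHPC": 6}
    )
    theta_freq: float = 8.0
    theta_amp: float = 60.0          # µV, median envelope
    env_sigma: float = 0.5           # log-normal envelope spread
    noise_exponent: float = 1.5      # 1/f^beta background slope
    noise_rms: float = 20.0          # µV, regional background
    channel_noise_rms: float = 8.0   # µV, per-channel independent noise
    line_amp: float = 5.0            # µV, 60 Hz fundamental
    bad_channel_prob: float = 0.0
    speed_mean: float = 10.0         # cm/s, OU stationary mean
    speed_sd: float = 5.0            # cm/s, OU stationary sd
    speed_tau: float = 10.0          # s, OU relaxation time
    px_per_cm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        ids = [s for s, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        for sid, sex in self.subjects:
            if sex not in ("F", "M"):
                raise ValueError(f"sex must be 'F' or 'M', got {sex!r} for {sid}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fs_raw < 2000:
            raise ValueError("fs_raw must be >= 2000 Hz")
        for sid, n in zip(ids, self.trial_counts()):
            if n < 1:
                raise ValueError(f"trials_per_subject must be >= 1 (subject {sid})")
        sexes = dict(self.subjects)
        for sid, stages in self.estrous_schedule.items():
            if sid not in sexes:
                raise ValueError(f"estrous schedule for unknown subject {sid!r}")
            if sexes[sid] != "F":
                raise ValueError(f"estrous schedule given for male subject {sid!r}")
            bad = set(stages) - set(ESTROUS_STAGES)
            if bad:
                raise ValueError(f"unknown estrous labels {bad} for subject {sid!r}")

    def trial_counts(self) -> tuple[int, ...]:
        if isinstance(self.trials_per_subject, int):
            return tuple([self.trials_per_subject] * len(self.subjects))
        if len(self.trials_per_subject) != len(self.subjects):
            raise ValueError("per-subject trial counts must match number of subjects")
        return tuple(self.trials_per_subject)

    def coupling_for(self, sex: str) -> tuple[CouplingSpec, ...]:
        return self.group_coupling.get(sex, self.coupling)


@dataclass
class TrialRecording:
    """One 10-minute (by default) session: raw channel LFPs plus tracking.

    ``lfp`` maps region label to a (channels x samples) float32 array in µV.
    ``tracking_xy`` is (2 x frames) pixel coordinates at 30 Hz.
    ``ground_truth`` carries synthetic-only extras (true speed trace, bad
    channel masks) that no real recording would provide; analysis code must
    not read it.
    """

    subject_id: str
    sex: str
    estrous: str
    fs: float
    lfp: dict[str, np.ndarray]
    tracking_xy: np.ndarray
    px_per_cm: float
    t0: float = 0.0
    trial_id: str = ""
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {v.shape[1] for v in self.lfp.values()}
        if len(lengths) > 1:
            raise ValueError("all regions must share sample count")
        if (self.sex == "M") != (self.estrous == "none"):
            raise ValueError("estrous must be 'none' iff sex is 'M'")

    @property
    def n_samples(self) -> int:
        return next(iter(self.lfp.values())).shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# --------------------------------------------------------------------------
# Table 1 template
# --------------------------------------------------------------------------

_TABLE1_TRIALS = {
    "F1": 25, "F2": 28, "F3": 23, "F4": 26, "F5": 28,
    "M1": 27, "M2": 27, "M3": 27, "M4": 25,
}
_TABLE1_ESTROUS = {  # (diestrus, proestrus, estrus, metestrus) counts
    "F1": (13, 3, 6, 3),
    "F2": (14, 9, 2, 3),
    "F3": (14, 3, 5, 1),
    "F4": (13, 7, 5, 1),
    "F5": (12, 6, 9, 1),
}


def _interleaved_schedule(counts: tuple[int, int, int, int]) -> tuple[str, ...]:
    """Round-robin the stages so a subject's trials cycle through them."""
    remaining = list(counts)
    out: list[str] = []
    while any(remaining):
        for i, stage in enumerate(ESTROUS_STAGES):
            if remaining[i] > 0:
                out.append(stage)
                remaining[i] -= 1
    return tuple(out)


def table1_cohort_config(duration_s: float = 600.0, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort layout matching the study: 5 females, 4 males, 23–28 trials each
    (236 total), with the per-female estrous stage multiplicities."""
    subjects = tuple((sid, "F" if sid.startswith("F") else "M") for sid in _TABLE1_TRIALS)
    trials = tuple(_TABLE1_TRIALS[sid] for sid, _ in subjects)
    schedule = {sid: _interleaved_schedule(c) for sid, c in _TABLE1_ESTROUS.items()}
    return CohortConfig(
        subjects=subjects,
        trials_per_subject=trials,
        estrous_schedule=schedule,
        duration_s=duration_s,
        seed=seed,
        **overrides,
    )


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------

def _theta_phase(n: int, fs: float, theta_freq: float, freq_jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unwrapped theta phase with per-cycle uniform frequency jitter."""
    n_cycles = int(math.ceil(n / fs * (theta_freq + freq_jitter))) + 2
    freqs = rng.uniform(theta_freq - freq_jitter, theta_freq + freq_jitter, n_cycles)
    cycle_edges = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    t = np.arange(n) / fs
    return np.interp(t, cycle_edges, 2 * np.pi * np.arange(n_cycles + 1))


def _per_cycle_to_samples(phase: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Map per-cycle values to samples, constant within each cycle.

    The piecewise-constant (phase-resetting) construction keeps each cycle's
    lag an exact draw from the configured distribution; smoothing the lag
    between cycles would drag independent draws through intermediate values
    and distort the lag marginal.
    """
    idx = np.clip(np.floor(phase / (2 * np.pi)).astype(np.intp), 0, len(values) - 1)
    return values[idx]


def latent_envelope_corr(rho: float, sigma: float) -> float:
    """Latent Gaussian correlation giving log-normal envelope correlation rho.

    corr(exp(s*z1), exp(s*z2)) = (exp(rho_g s^2) - 1) / (exp(s^2) - 1); the
    inverse is found numerically. Raises if rho is below the log-normal
    attainable minimum.
    """
    if rho == 0.0:
        return 0.0
    s2 = sigma * sigma

    def fwd(rho_g):
        return math.expm1(rho_g * s2) / math.expm1(s2) - rho

    lo, hi = -1.0, 1.0
    if fwd(lo) > 0:
        raise ValueError(f"envelope_rho={rho} unattainable for sigma={sigma}")
    return brentq(fwd, lo, hi, xtol=1e-12)


def _envelope_pair(n: int, fs: float, rho: float, sigma: float, amp: float,
                   window_s: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Correlated log-normal amplitude envelopes, piecewise per window."""
    n_win = max(2, int(math.ceil(n / fs / window_s)) + 1)
    rho_g = latent_envelope_corr(rho, sigma)
    z1 = rng.standard_normal(n_win)
    z2 = rho_g * z1 + math.sqrt(max(0.0, 1 - rho_g**2)) * rng.standard_normal(n_win)
    e1 = amp * np.exp(sigma * z1)
    e2 = amp * np.exp(sigma * z2)
    t = np.arange(n) / fs
    mids = (np.arange(n_win) + 0.5) * window_s
    return np.interp(t, mids, e1), np.interp(t, mids, e2)


def one_over_f_noise(n: int, fs: float, exponent: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f^exponent."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    x *= rms / np.sqrt(np.mean(x * x))
    return x


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def simulate_region_pair(duration_s: float, fs: float, theta_freq: float,
                         spec: CouplingSpec, noise_exponent: float = 1.5,
                         seed: int = 0, *, theta_amp: float = 60.0,
                         noise_rms: float = 20.0, env_sigma: float = 0.5,
                         env_window_s: float = 2.5, freq_jitter: float = 1.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one coupled region pair (driver, follower).

    The follower's theta phase lags the driver's by an independent
    von Mises(phase_lag_mean, phase_kappa) draw each driver cycle; amplitude
    envelopes are correlated log-normals; 1/f background noise is added to
    both. Set ``noise_rms=0`` for a noiseless pair. Fully reproducible under
    a fixed seed.
    """
    if not 4.0 <= theta_freq <= 12.0:
        raise ValueError("theta_freq must lie in the theta band [4, 12] Hz")
    n = int(round(duration_s * fs))
    if n < 2 * fs / theta_freq:
        raise ValueError("trace must span at least 2 theta cycles")
    rng = np.random.default_rng(seed)
    phase = _theta_phase(n, fs, theta_freq, freq_jitter, rng)
    n_cycles = int(phase[-1] / (2 * np.pi)) + 2
    lags = rng.vonmises(spec.phase_lag_mean, spec.phase_kappa, n_cycles) \
        if spec.phase_kappa > 0 else rng.uniform(-np.pi, np.pi, n_cycles)
    lag_t = _per_cycle_to_samples(phase, lags)
    env_a, env_b = _envelope_pair(n, fs, spec.envelope_rho, env_sigma,
                                  theta_amp, env_window_s, rng)
    a = env_a * np.cos(phase)
    b = env_b * np.cos(phase - lag_t)
    if noise_rms > 0:
        a = a + one_over_f_noise(n, fs, noise_exponent, noise_rms, rng)
        b = b + one_over_f_noise(n, fs, noise_exponent, noise_rms, rng)
    return a, b


def _simulate_tracking(duration_s: float, config: CohortConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """OU speed (reflected at 0) + drifting heading, integrated in the arena.

    Returns (xy_px [2 x frames], true_speed_cms [frames]).
    """
    n = int(round(duration_s * TRACK_FS))
    dt = 1.0 / TRACK_FS
    tau, mu = config.speed_tau, config.speed_mean
    sigma_ou = config.speed_sd * math.sqrt(2.0 / tau)
    speed = np.empty(n)
    s = abs(rng.normal(mu, config.speed_sd))
    kicks = rng.standard_normal(n) * sigma_ou * math.sqrt(dt)
    for i in range(n):
        s = s + (mu - s) * dt / tau + kicks[i]
        s = abs(s)  # reflect at 0
        speed[i] = s
    heading = np.cumsum(rng.standard_normal(n) * 0.6 * math.sqrt(dt))
    heading += rng.uniform(0, 2 * np.pi)
    steps = np.stack([np.cos(heading), np.sin(heading)]) * speed * dt
    xy = np.cumsum(steps, axis=1)
    xy += np.array([[ARENA_CM / 2], [ARENA_CM / 2]])
    # reflect into the arena (triangle-wave fold)
    xy = np.abs(np.mod(xy, 2 * ARENA_CM) - ARENA_CM)
    xy = ARENA_CM - xy
    return (xy * config.px_per_cm).astype(np.float64), speed


def _trial_seed(config: CohortConfig, subject_index: int, trial_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, subject_index, trial_index])


def simulate_trial(config: CohortConfig, subject_id: str, trial_index: int,
                   seed: int | None = None) -> TrialRecording:
    """Simulate one session for ``subject_id``.

    Four regional signals are built from two independent hippocampal theta
    drivers; each prefrontal region follows the hippocampal region with which
    its configured coupling is strongest. Channel bundles share the regional
    signal plus independent channel noise; with probability
    ``bad_channel_prob`` a channel is replaced by pure independent noise.
    60 Hz line interference and six harmonics are added to every channel.
    """
    ids = [s for s, _ in config.subjects]
    if subject_id not in ids:
        raise ValueError(f"unknown subject {subject_id!r}")
    si = ids.index(subject_id)
    sex = dict(config.subjects)[subject_id]
    if seed is None:
        ss = _trial_seed(config, si, trial_index)
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    fs, n = config.fs_raw, int(round(config.duration_s * config.fs_raw))
    specs = {sp.region_pair: sp for sp in config.coupling_for(sex)}

    # hippocampal drivers: independent theta phases
    phases = {r: _theta_phase(n, fs, config.theta_freq, 1.0, rng) for r in HPC_REGIONS}
    regional: dict[str, np.ndarray] = {}
    envelopes: dict[str, np.ndarray] = {}
    for r in HPC_REGIONS:
        env, _ = _envelope_pair(n, fs, 0.0, config.env_sigma, config.theta_amp, 2.5, rng)
        envelopes[r] = env
        regional[r] = env * np.cos(phases[r])

    # each mPFC region follows its strongest-coupled hippocampal driver
    for m in MPFC_REGIONS:
        cands = [specs[(h, m)] for h in HPC_REGIONS if (h, m) in specs]
        if not cands:
            raise ValueError(f"no coupling spec involves mPFC region {m}")
        sp = max(cands, key=lambda s: s.phase_kappa)
        driver = sp.region_pair[0]
        phase_d = phases[driver]
        n_cycles = int(phase_d[-1] / (2 * np.pi)) + 2
        lags = rng.vonmises(sp.phase_lag_mean, sp.phase_kappa, n_cycles) \
            if sp.phase_kappa > 0 else rng.uniform(-np.pi, np.pi, n_cycles)
        lag_t = _per_cycle_to_samples(phase_d, lags)
        # follower envelope correlated with the driver's realized envelope
        rho_g = latent_envelope_corr(sp.envelope_rho, config.env_sigma)
        z_d = np.log(envelopes[driver] / config.theta_amp) / config.env_sigma
        z_f = rho_g * z_d + math.sqrt(max(0.0, 1 - rho_g**2)) * \
            _per_cycle_to_samples(phase_d, rng.standard_normal(n_cycles))
        env_f = config.theta_amp * np.exp(config.env_sigma * z_f)
        regional[m] = env_f * np.cos(phase_d - lag_t)

    # line noise shared across channels of the trial
    t = np.arange(n) / fs
    line = np.zeros(n)
    if config.line_amp > 0:
        line_phases = rng.uniform(0, 2 * np.pi, 7)
        for k in range(1, 8):
            line += (config.line_amp / k) * np.sin(2 * np.pi * 60.0 * k * t + line_phases[k - 1])

    lfp: dict[str, np.ndarray] = {}
    bad_channels: dict[str, np.ndarray] = {}
    for r in REGIONS:
        n_ch = config.n_channels[r]
        base = regional[r] + one_over_f_noise(n, fs, config.noise_exponent,
                                              config.noise_rms, rng)
        chans = np.empty((n_ch, n), dtype=np.float32)
        bad = rng.random(n_ch) < config.bad_channel_prob
        sig_rms = float(np.sqrt(np.mean(base * base)))
        for c in range(n_ch):
            if bad[c]:
                chans[c] = (one_over_f_noise(n, fs, config.noise_exponent, sig_rms, rng)
                            + line).astype(np.float32)
            else:
                chans[c] = (base
                            + one_over_f_noise(n, fs, config.noise_exponent,
                                               config.channel_noise_rms, rng)
                            + line).astype(np.float32)
        lfp[r] = chans
        bad_channels[r] = bad

    xy, true_speed = _simulate_tracking(config.duration_s, config, rng)

    schedule = config.estrous_schedule.get(subject_id)
    if sex == "M":
        estrous = "none"
    elif schedule is not None and trial_index < len(schedule):
        estrous = schedule[trial_index]
    else:
        estrous = "diestrus"

    return TrialRecording(
        subject_id=subject_id, sex=sex, estrous=estrous, fs=fs, lfp=lfp,
        tracking_xy=xy, px_per_cm=config.px_per_cm,
        t0=trial_index * config.duration_s,
        trial_id=f"{subject_id}_t{trial_index:03d}",
        ground_truth={"true_speed_cms": true_speed, "bad_channels": bad_channels},
    )


def simulate_scalar_cohort(subject_trials: dict[str, int], mean: float,
                           subject_sd: float = 0.4, trial_sd: float = 0.8,
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Trial-level scalar values with a subject random effect.

    Generates, per subject, ``n_trials`` values mean + b_s + e_t with
    b_s ~ N(0, subject_sd^2) and e_t ~ N(0, trial_sd^2) — the nested
    structure the hierarchical bootstrap is designed for. The default
    spreads match the scale of per-trial phase-lag widths (radians).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sid, n_tr in subject_trials.items():
        out[sid] = mean + rng.normal(0.0, subject_sd) + rng.normal(0.0, trial_sd, n_tr)
    return out


def simulate_cohort(config: CohortConfig) -> list[TrialRecording]:
    """Simulate every trial in the configured cohort, deterministically.

    Trial counts, sexes and estrous label multiplicities follow the schedule;
    with the :func:`table1_cohort_config` template this yields 236 trials.
    """
    counts = config.trial_counts()
    for (sid, _), n_tr in zip(config.subjects, counts):
        sched = config.estrous_schedule.get(sid)
        if sched is not None and len(sched) != n_tr:
            raise ValueError(
                f"estrous schedule length {len(sched)} != trial count {n_tr} for {sid}")
    return [
        simulate_trial(config, sid, k)
        for (sid, _), n_tr in zip(config.subjects, counts)
        for k in range(n_tr)
    ]
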