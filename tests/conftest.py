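import numpy as np
import pytest

from thetalink.synthetic import CohortConfig, CouplingSpec, simulate_trial

FS = 2000.0


def circular_mean(angles):
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles)))))


def circular_variance(angles):
    return float(1.0 - np.abs(np.mean(np.exp(1j * np.asarray(angles)))))


def measured_phase_lags(a, b, fs=FS):
    """Hilbert instantaneous phase difference of theta-filtered traces."""
    from scipy.signal import hilbert

    from thetalink.theta_coupling import theta_filter, wrap_phase

    fa = theta_filter(a, fs)
    fb = theta_filter(b, fs)
    return wrap_phase(np.angle(hilbert(fa)) - np.angle(hilbert(fb)))


@pytest.fixture(scope="session")
def small_cohort_config():
    """2 F + 2 M subjects, 3 short trials each: fast but fully structured."""
    return CohortConfig(
        subjects=(("F1", "F"), ("F2", "F"), ("M1", "M"), ("M2", "M")),
        trials_per_subject=3,
        duration_s=30.0,
        estrous_schedule={
            "F1": ("diestrus", "proestrus", "estrus"),
            "F2": ("diestrus", "proestrus", "estrus"),
        },
        seed=42,
    )


@pytest.fixture(scope="session")
def one_trial(small_cohort_config):
    return simulate_trial(small_cohort_config, "F1", 0)


@pytest.fixture
def tight_pair():
    spec = CouplingSpec(("vHPC", "PrL"), phase_lag_mean=0.4, phase_kappa=50.0,
                        envelope_rho=0.5)
    from thetalink.synthetic import simulate_region_pair

    return simulate_region_pair(120.0, FS, 8.0, spec, seed=7)
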