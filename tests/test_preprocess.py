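"""Preprocessing contracts: cleaning, PLV QC, regional mean, velocity gating."""

import numpy as np
import pytest
from scipy import signal

from thetalink.preprocess import (
    ANALYSIS_FS,
    channel_qc,
    clean_channel,
    compute_velocity,
    concatenate_epochs,
    plv_matrix,
    preprocess_trial,
    regional_lfp,
    velocity_epochs,
)
from thetalink.preprocess import RegionalLFPSet, VelocityEpochs

FS = ANALYSIS_FS


def _bin_power(x, freq, fs):
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return np.abs(np.fft.rfft(x))[np.argmin(np.abs(f - freq))] ** 2


class TestCleanChannel:
    def test_passband_identity_at_8hz(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 8 * t)
        y = clean_channel(x, FS)
        core = slice(4000, -4000)
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.05)
        lags = signal.correlate(y[core], x[core], mode="full")
        assert np.argmax(lags) == len(x[core]) - 1  # zero phase shift

    def test_line_attenuated_theta_preserved(self):
        """8 Hz + equal-amplitude 60 Hz: >= 20 dB down at 60 Hz, < 1 dB
        change at 8 Hz (FFT-bin oracle)."""
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 60 * t)
        y = clean_channel(x, FS)
        for f0, min_db in [(60, 20), (120, 20), (420, 20)]:
            xh = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * f0 * t)
            yh = clean_channel(xh, FS)
            atten = 10 * np.log10(_bin_power(xh, f0, FS) / _bin_power(yh, f0, FS))
            assert atten >= min_db
        change = 10 * np.log10(_bin_power(x, 8, FS) / _bin_power(y, 8, FS))
        assert abs(change) < 1.0

    def test_dc_offset_removed(self):
        y = clean_channel(np.full(int(60 * FS), 100.0), FS)
        assert abs(y.mean()) < 1.0

    def test_decimation_from_32k(self):
        fs_in = 32000.0
        t = np.arange(0, 4, 1 / fs_in)
        y = clean_channel(np.sin(2 * np.pi * 8 * t), fs_in)
        assert len(y) == int(4 * FS)
        assert np.max(np.abs(y[2000:-2000])) == pytest.approx(1.0, rel=0.05)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            clean_channel(np.zeros(1000), 1000.0)


class TestChannelQC:
    @staticmethod
    def _shared_bundle(n_ch, n, snr=10.0, seed=0):
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(n)
        return np.stack([shared + rng.standard_normal(n) / snr
                         for _ in range(n_ch)])

    def test_plv_matches_direct_formula_oracle(self):
        """plv_matrix equals |mean(e^{i d-phi})| per frequency averaged over
        the band, computed by an explicit loop over windows and tapers."""
        rng = np.random.default_rng(1)
        chans = np.stack([rng.standard_normal(20_000),
                          rng.standard_normal(20_000)])
        got = plv_matrix(chans, FS)[0, 1]
        nper = int(2.0 * FS)
        tapers = signal.windows.dpss(nper, 3.0, 5)
        freqs = np.fft.rfftfreq(nper, 1 / FS)
        band = (freqs >= 0.5) & (freqs <= 100.0)
        phasors = []
        for w in range(chans.shape[1] // nper):
            seg = chans[:, w * nper:(w + 1) * nper]
            for k in range(5):
                fa = np.fft.rfft(seg[0] * tapers[k])
                fb = np.fft.rfft(seg[1] * tapers[k])
                dphi = np.angle(fa) - np.angle(fb)
                phasors.append(np.exp(1j * dphi[band]))
        expected = float(np.mean(np.abs(np.mean(phasors, axis=0))))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_shared_signal_channels_all_kept(self):
        chans = self._shared_bundle(6, 60_000)
        reports = channel_qc({"dHPC": chans}, FS)
        rep = reports["dHPC"]
        assert rep.kept_mask.all()
        off = rep.plv_matrix[~np.eye(6, dtype=bool)]
        assert (off > 0.9).all()

    def test_noise_channel_excluded(self):
        rng = np.random.default_rng(2)
        chans = self._shared_bundle(5, 60_000, seed=3)
        chans = np.vstack([chans, rng.standard_normal(60_000)[None, :]])
        rep = channel_qc({"vHPC": chans}, FS)["vHPC"]
        assert rep.kept_mask.tolist() == [True] * 5 + [False]

    def test_all_noise_region_is_hard_error(self):
        rng = np.random.default_rng(4)
        chans = rng.standard_normal((2, 60_000))
        with pytest.raises(ValueError, match="vHPC"):
            channel_qc({"vHPC": chans}, FS)

    def test_qc_idempotent_on_kept_channels(self):
        rng = np.random.default_rng(5)
        chans = self._shared_bundle(5, 60_000, seed=6)
        chans = np.vstack([chans, rng.standard_normal(60_000)[None, :]])
        rep1 = channel_qc({"IL": chans}, FS)["IL"]
        rep2 = channel_qc({"IL": chans[rep1.kept_mask]}, FS)["IL"]
        assert rep2.kept_mask.all()

    def test_manual_flags_respected(self):
        chans = self._shared_bundle(4, 40_000, seed=7)
        flags = np.array([True, False, False, False])
        rep = channel_qc({"PrL": chans}, FS, manual_flags={"PrL": flags})["PrL"]
        assert not rep.kept_mask[0] and rep.kept_mask[1:].all()


class TestRegionalLFP:
    def test_single_kept_channel_is_identity(self):
        x = np.random.default_rng(0).standard_normal((3, 100))
        out = regional_lfp(x, np.array([False, True, False]))
        np.testing.assert_array_equal(out, x[1])

    def test_opposite_channels_cancel(self):
        x = np.random.default_rng(1).standard_normal(100)
        out = regional_lfp(np.stack([x, -x]), np.array([True, True]))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_brute_force_mean(self):
        x = np.random.default_rng(2).standard_normal((4, 50))
        mask = np.array([True, False, True, True])
        np.testing.assert_allclose(regional_lfp(x, mask), x[mask].mean(axis=0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="kept"):
            regional_lfp(np.zeros((2, 10)), np.array([False, False]))


class TestVelocity:
    def test_stationary_animal_zero_velocity(self):
        xy = np.full((2, 300), 55.0)
        v = compute_velocity(xy, 30.0, 5.0, 20_000)
        assert np.max(np.abs(v)) < 1e-9

    def test_constant_speed_recovered(self):
        """Straight line at 10 cm/s: central 40 s within 0.2 cm/s."""
        frames = np.arange(60 * 30)
        xy = np.stack([10.0 / 30.0 * 5.0 * frames, np.zeros_like(frames, float)])
        v = compute_velocity(xy, 30.0, 5.0, int(60 * FS))
        central = v[int(10 * FS):int(50 * FS)]
        assert np.max(np.abs(central - 10.0)) < 0.2

    def test_px_per_cm_scale_equivariance(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.standard_normal((2, 900)), axis=1)
        v1 = compute_velocity(xy, 30.0, 4.0, 20_000)
        v2 = compute_velocity(xy, 30.0, 8.0, 20_000)
        np.testing.assert_allclose(v2, v1 / 2.0, rtol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            compute_velocity(np.zeros((2, 1)), 30.0, 5.0, 100)


class TestVelocityEpochs:
    def test_alternating_blocks_brute_force(self):
        """3/10/20 cm/s in 2 s blocks: only the 10 cm/s blocks survive."""
        block = int(2 * FS)
        v = np.concatenate([np.full(block, s) for s in (3.0, 10.0, 20.0) * 3])
        eps = velocity_epochs(v)
        # brute-force scan oracle
        ok = (v >= 5) & (v <= 15)
        expected = []
        start = None
        for i, flag in enumerate(ok):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                expected.append((start, i))
                start = None
        if start is not None:
            expected.append((start, len(v)))
        expected = [(s, e) for s, e in expected if e - s >= int(0.5 * FS)]
        assert eps.intervals == expected
        assert all(e - s == block for s, e in eps.intervals)

    def test_constant_in_band_single_interval(self):
        v = np.full(10_000, 10.0)
        assert velocity_epochs(v).intervals == [(0, 10_000)]

    def test_constant_out_of_band_empty(self):
        assert velocity_epochs(np.full(10_000, 2.0)).intervals == []

    def test_short_runs_discarded(self):
        v = np.full(10_000, 2.0)
        v[100:400] = 10.0  # 0.15 s, below the 0.5 s minimum
        assert velocity_epochs(v).intervals == []


class TestConcatenate:
    @staticmethod
    def _rset(n, seed, fs=FS):
        rng = np.random.default_rng(seed)
        traces = {r: rng.standard_normal(n) for r in ("PrL", "IL", "vHPC", "dHPC")}
        return RegionalLFPSet(fs=fs, traces=traces, velocity=np.full(n, 10.0))

    def test_single_epoch_identity_slice(self):
        rs = self._rset(5000, 0)
        out = concatenate_epochs([rs], [VelocityEpochs([(1000, 3000)])])
        for r in rs.traces:
            np.testing.assert_array_equal(out.traces[r], rs.traces[r][1000:3000])
        assert out.boundaries == []

    def test_boundary_bookkeeping(self):
        rs = self._rset(20_000, 1)
        eps = VelocityEpochs([(0, int(2 * FS)), (10_000, 10_000 + int(3 * FS))])
        out = concatenate_epochs([rs], [eps])
        assert out.n_samples == int(5 * FS)
        assert out.boundaries == [int(2 * FS)]

    def test_total_duration_sum_oracle(self):
        trials = [self._rset(20_000, s) for s in range(3)]
        eps = [VelocityEpochs([(0, 4000), (6000, 9000)]),
               VelocityEpochs([(100, 2100)]),
               VelocityEpochs([(0, 20_000)])]
        out = concatenate_epochs(trials, eps)
        assert out.n_samples == sum(e.total_samples() for e in eps)

    def test_cross_region_alignment_preserved(self):
        """Any concatenated sample index maps to one original timestamp in
        all four regions."""
        rs = self._rset(20_000, 2)
        # tag each region with a distinct linear ramp so indices are decodable
        for k, r in enumerate(rs.traces):
            rs.traces[r] = np.arange(20_000, dtype=float) + k * 1e6
        out = concatenate_epochs([rs], [VelocityEpochs([(5, 1005), (2000, 3000)])])
        base = out.traces["PrL"] % 1e6
        for r in out.traces:
            np.testing.assert_array_equal(out.traces[r] % 1e6, base)

    def test_mismatched_fs_rejected(self):
        a, b = self._rset(2000, 0), self._rset(2000, 1, fs=1000.0)
        with pytest.raises(ValueError, match="rate"):
            concatenate_epochs([a, b], [VelocityEpochs([(0, 2000)])] * 2)


def test_preprocess_trial_end_to_end(one_trial):
    rset = preprocess_trial(one_trial)
    n = rset.n_samples
    assert set(rset.traces) == {"PrL", "IL", "vHPC", "dHPC"}
    assert all(len(t) == n for t in rset.traces.values())
    assert (rset.velocity >= 0).all()
    assert all(rep.kept_mask.any() for rep in rset.qc.values())
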