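import numpy as np
import pytest

from eegdyn import (
    Segment,
    WaveletConfig,
    ccorr,
    morlet_phase,
    ps_norm_series,
    ps_norm_stats,
    sliding_sync,
)
from eegdyn.phase import TFPhase, _sliding_sync_direct, connection_pairs


class TestWaveletConfig:
    def test_time_frequency_uncertainty_product(self):
        cfg = WaveletConfig()
        for f in cfg.freqs:
            assert cfg.sigma_t(f) * cfg.sigma_f(f) == pytest.approx(
                1 / (2 * np.pi))

    def test_default_ten_bins_2_to_20(self):
        assert WaveletConfig().freqs == tuple(float(f) for f in range(2, 21, 2))


class TestMorletPhase:
    def test_unit_sinusoid_unit_magnitude(self, sinusoid_segment):
        tf = morlet_phase(sinusoid_segment, WaveletConfig(freqs=(10.0,)),
                          keep_coefficients=True)
        mid = np.abs(tf.coefficients[0, 0, 1000:1500])
        np.testing.assert_allclose(mid, 1.0, rtol=0.01)

    def test_phase_advance_rate(self, sinusoid_segment):
        tf = morlet_phase(sinusoid_segment, WaveletConfig(freqs=(10.0,)))
        inc = np.diff(np.unwrap(tf.phase[0, 0, 1000:1500]))
        np.testing.assert_allclose(inc, 2 * np.pi * 10 / 250, rtol=0.01)

    def test_quarter_cycle_lag_recovered(self):
        t = np.arange(2500) / 250.0
        x = np.vstack([np.cos(2 * np.pi * 10 * t),
                       np.cos(2 * np.pi * 10 * t - np.pi / 2)])
        seg = Segment(x - x.mean(axis=1, keepdims=True), 250.0, ("a", "b"))
        tf = morlet_phase(seg, WaveletConfig(freqs=(10.0,)))
        dphi = np.angle(np.exp(1j * (tf.phase[0, 0, 1000:1500]
                                     - tf.phase[1, 0, 1000:1500])))
        np.testing.assert_allclose(dphi, np.pi / 2, atol=0.02)

    def test_white_noise_band_pass_increment(self, rng):
        x = rng.standard_normal((1, 5000))
        seg = Segment(x - x.mean(), 250.0, ("a",))
        tf = morlet_phase(seg, WaveletConfig(freqs=(10.0,)))
        inc = np.diff(np.unwrap(tf.phase[0, 0, 500:4500]))
        circ_mean = np.angle(np.mean(np.exp(1j * inc)))
        assert circ_mean == pytest.approx(2 * np.pi * 10 / 250, rel=0.05)

    def test_kernel_longer_than_segment_rejected(self):
        seg = Segment(np.zeros((1, 200)), 250.0, ("a",))
        with pytest.raises(ValueError, match="support"):
            morlet_phase(seg, WaveletConfig(freqs=(2.0,)))


class TestCCorr:
    def test_identical_windows_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 100)
        assert ccorr(phi, phi) == 1.0

    def test_anticovarying_windows_minus_one(self, rng):
        # deviations of -phi are the negated deviations of phi
        phi = rng.uniform(-np.pi, np.pi, 100)
        assert ccorr(phi, -phi) == -1.0

    def test_constant_pi_offset_gives_plus_one_unwrapped(self, rng):
        # the formula measures phase covariance: a common offset added
        # without wrapping shifts the reference identically
        phi = rng.uniform(-np.pi, np.pi, 100)
        assert ccorr(phi, phi + np.pi) == pytest.approx(1.0)

    def test_independent_phases_near_zero(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(1000):
            a = rng.uniform(-np.pi, np.pi, 251)
            b = rng.uniform(-np.pi, np.pi, 251)
            hits += abs(ccorr(a, b)) < 0.2
        assert hits >= 950

    def test_degenerate_window_flagged(self):
        phi = np.zeros(10)
        assert np.isnan(ccorr(phi, phi))

    def test_reference_convention_pinned(self):
        # regression pin of the arithmetic-mean deviation reference
        phi_i = np.array([0.1, 0.5, -0.3, 0.9, -0.7, 0.2])
        phi_j = np.array([-0.2, 0.4, 0.1, 0.8, -0.9, 0.05])
        # hand recomputation: s_x = sin(x - mean(x)); sum(s_i*s_j)/sqrt(...)
        si = np.sin(phi_i - phi_i.mean())
        sj = np.sin(phi_j - phi_j.mean())
        expected = (si * sj).sum() / np.sqrt((si**2).sum() * (sj**2).sum())
        assert ccorr(phi_i, phi_j) == pytest.approx(0.8956301, abs=1e-6)
        assert ccorr(phi_i, phi_j) == pytest.approx(expected)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            ccorr(np.zeros(2), np.zeros(2))


class TestSlidingSync:
    def test_19_channels_171_connections(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (19, 600))
        tf = TFPhase(phase=phase[:, None, :], freqs=(10.0,), rate=250.0)
        ss = sliding_sync(tf, 251, 25)
        assert ss.n_connections == 171
        assert len(connection_pairs(19)) == 171

    def test_full_overlap_center_count(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (4, 2500))
        tf = TFPhase(phase=phase[:, None, :], freqs=(10.0,), rate=250.0)
        ss = sliding_sync(tf, 251, 1)
        assert ss.n_windows == 2500 - 251 + 1 == 2250
        assert ss.n_connections == 6
        assert ss.window_centers[0] == 125
        assert ss.window_centers[-1] == 2500 - 126

    def test_expansion_matches_direct_computation(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (5, 400))
        tf = TFPhase(phase=phase[:, None, :], freqs=(8.0,), rate=250.0)
        fast = sliding_sync(tf, 101, 13)
        slow = _sliding_sync_direct(tf, 101, 13, "arithmetic", None)
        np.testing.assert_allclose(fast.values, slow.values, atol=1e-10)

    def test_time_reversal_reverses_windows(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (3, 500))
        tf = TFPhase(phase=phase[:, None, :], freqs=(10.0,), rate=250.0)
        rev = TFPhase(phase=phase[:, None, ::-1].copy(), freqs=(10.0,),
                      rate=250.0)
        a = sliding_sync(tf, 51, 1)
        b = sliding_sync(rev, 51, 1)
        np.testing.assert_allclose(a.values, b.values[:, :, ::-1], atol=1e-10)
        mu_a, _ = ps_norm_stats(ps_norm_series(a))
        mu_b, _ = ps_norm_stats(ps_norm_series(b))
        np.testing.assert_allclose(mu_a, mu_b)

    def test_window_longer_than_segment_rejected(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (2, 100))
        tf = TFPhase(phase=phase[:, None, :], freqs=(10.0,), rate=250.0)
        with pytest.raises(ValueError):
            sliding_sync(tf, 251, 1)


class TestPSNorm:
    def _series(self, values):
        n_con, n_win = values.shape
        from eegdyn.phase import SyncSeries, connection_pairs
        n_ch = int((1 + np.sqrt(1 + 8 * n_con)) / 2)
        return SyncSeries(
            values=values[None], freqs=(10.0,),
            window_centers=np.arange(n_win) + 125, rate=250.0,
            window_samples=251, step_samples=1,
            pairs=connection_pairs(n_ch), segment_duration=10.0)

    def test_unit_connections_unit_norm(self):
        ss = self._series(np.ones((6, 5)))
        np.testing.assert_allclose(ps_norm_series(ss), 1.0)

    def test_zero_connections_zero_norm(self):
        ss = self._series(np.zeros((6, 5)))
        np.testing.assert_allclose(ps_norm_series(ss), 0.0)

    def test_constant_connections_absolute_value(self):
        ss = self._series(np.full((6, 5), -0.4))
        np.testing.assert_allclose(ps_norm_series(ss), 0.4)

    def test_norm_bounded_by_extremes(self, rng):
        vals = rng.uniform(-1, 1, (10, 20))
        ss = self._series(vals)
        norm = ps_norm_series(ss)
        assert np.all(norm <= np.abs(vals).max(axis=0) + 1e-12)
        assert np.all((norm >= 0) & (norm <= 1))

    def test_stats_hand_example(self):
        mu, sd = ps_norm_stats(np.array([[0.0, 1.0]]))
        assert mu[0] == pytest.approx(0.5)
        assert sd[0] == pytest.approx(np.sqrt(0.5))  # sample SD 0.7071

    def test_constant_series_zero_sd(self):
        mu, sd = ps_norm_stats(np.full((1, 8), 0.3))
        assert (mu[0], sd[0]) == (pytest.approx(0.3), pytest.approx(0.0))

    def test_flagged_windows_excluded(self):
        series = np.array([[0.2, np.nan, 0.4]])
        mu, sd = ps_norm_stats(series)
        assert mu[0] == pytest.approx(0.3)

    def test_switching_fixture_more_variable_than_stationary(
            self, stationary_segment, switching_segment, wavelet_10hz):
        def sigma_ps(seg):
            tf = morlet_phase(seg, wavelet_10hz)
            ss = sliding_sync(tf, 251, 25)
            _, sd = ps_norm_stats(ps_norm_series(ss))
            return sd[0]
        assert sigma_ps(switching_segment) > sigma_ps(stationary_segment)
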