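"""Detrending, normalization, smoothing and EEMD behavior."""

import numpy as np
import pytest

from lassa.preprocess import (
    IMFSet,
    PreprocConfig,
    detrend_smoothness_prior,
    eemd,
    emd,
    moving_average,
    normalize,
    select_imf_by_band,
)


def detrend_oracle(x, lam):
    """Dense direct solve of the smoothness-prior system at small N."""
    n = x.size
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = [1.0, -2.0, 1.0]
    trend = np.linalg.solve(np.eye(n) + lam**2 * d2.T @ d2, x)
    return x - trend


class TestDetrend:
    def test_constant_series_is_pure_trend(self):
        np.testing.assert_allclose(
            detrend_smoothness_prior(np.full(50, 3.7), 300.0), 0.0, atol=1e-9
        )

    def test_lambda_zero_returns_zeros(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_array_equal(detrend_smoothness_prior(x, 0.0), 0.0)

    def test_linear_ramp_absorbed_at_large_lambda(self):
        x = np.linspace(0.0, 10.0, 200)
        out = detrend_smoothness_prior(x, 1e4)
        assert np.max(np.abs(out)) < 0.01 * 10.0

    def test_matches_dense_oracle(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(
            detrend_smoothness_prior(x, 25.0), detrend_oracle(x, 25.0), atol=1e-8
        )

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 60))
        lhs = detrend_smoothness_prior(2.0 * x + 3.0 * y, 100.0)
        rhs = 2.0 * detrend_smoothness_prior(x, 100.0) + 3.0 * detrend_smoothness_prior(y, 100.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            detrend_smoothness_prior(np.array([1.0, np.nan, 2.0]), 10.0)


class TestNormalize:
    def test_zero_mean_unit_sd(self):
        y = normalize(np.array([1.0, 2.0, 3.0]))
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std() == pytest.approx(1.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        y = normalize(x)
        np.testing.assert_allclose(normalize(y), y, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(normalize(3.0 * x + 7.0), normalize(x), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.full(10, 2.0))


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(20, 5.0)), 5.0)

    def test_impulse_spread(self):
        x = np.zeros(11)
        x[5] = 1.0
        y = moving_average(x, 5)
        np.testing.assert_allclose(y[3:8], 0.2)
        np.testing.assert_allclose(y[[0, 1, 2, 8, 9, 10]], 0.0)

    def test_alternating_interior(self):
        x = np.array([1.0, -1.0] * 10)
        y = moving_average(x, 5)
        np.testing.assert_allclose(np.abs(y[2:-2]), 0.2)

    def test_edges_shrink_preserving_length(self):
        x = np.arange(10.0)
        y = moving_average(x, 5)
        assert y.size == 10
        assert y[0] == pytest.approx(np.mean(x[:3]))  # window clipped to 3 samples

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 4)


class TestEEMD:
    fps = 30.0

    def two_tone(self, n=900):
        t = np.arange(n) / self.fps
        return np.sin(2 * np.pi * 1.2 * t) + np.sin(2 * np.pi * 0.1 * t)

    def dominant_freq(self, x):
        f = np.fft.rfftfreq(1 << 13, 1 / self.fps)
        return f[np.argmax(np.abs(np.fft.rfft(x, 1 << 13)))]

    def test_high_frequency_tone_in_earlier_imf(self):
        s = eemd(self.two_tone(), PreprocConfig(), seed=3, fps=self.fps)
        freqs = [self.dominant_freq(imf) for imf in s.imfs]
        i_fast = min(i for i, f in enumerate(freqs) if abs(f - 1.2) < 0.3)
        i_slow = min(i for i, f in enumerate(freqs) if abs(f - 0.1) < 0.05)
        assert i_fast < i_slow

    def test_reconstruction_within_ensemble_noise_bound(self):
        cfg = PreprocConfig()
        x = self.two_tone()
        s = eemd(x, cfg, seed=3, fps=self.fps)
        err = np.linalg.norm(s.reconstruct() - x) / np.linalg.norm(x)
        assert err <= 2 * cfg.eemd_noise_std / np.sqrt(cfg.eemd_ensembles) + 1e-3

    def test_seed_determinism(self):
        cfg = PreprocConfig(eemd_ensembles=10)
        a = eemd(self.two_tone(300), cfg, seed=9, fps=self.fps)
        b = eemd(self.two_tone(300), cfg, seed=9, fps=self.fps)
        assert len(a.imfs) == len(b.imfs)
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ia, ib)

    def test_plain_emd_imf_extrema_zero_crossing_balance(self):
        # IMF definition: extrema and zero-crossing counts differ by at most 1
        imfs, _ = emd(self.two_tone())
        for imf in imfs[:3]:
            d = np.diff(np.sign(np.diff(imf)))
            n_ext = np.count_nonzero(d)
            n_zc = np.count_nonzero(np.diff(np.signbit(imf[np.abs(imf) > 1e-12])))
            assert abs(n_ext - n_zc) <= 1

    def test_monotone_input_gives_pure_residual(self):
        s = eemd(np.linspace(0, 1, 20), PreprocConfig(eemd_noise_std=0.0), seed=0)
        assert s.imfs == []
        np.testing.assert_allclose(s.residual, np.linspace(0, 1, 20))


class TestSelectIMF:
    fps = 30.0

    def make_set(self, series):
        return IMFSet(imfs=list(series), residual=np.zeros_like(series[0]), fps=self.fps)

    def test_selects_strongest_in_band_imf(self, rng):
        t = np.arange(900) / self.fps
        tone = np.sin(2 * np.pi * 1.2 * t)
        drift = np.sin(2 * np.pi * 0.1 * t)
        noise = 0.1 * rng.normal(size=900)
        s = self.make_set([noise, tone, drift])
        np.testing.assert_array_equal(select_imf_by_band(s), tone)

    def test_band_restriction_ignores_out_of_band_energy(self):
        t = np.arange(900) / self.fps
        strong_out = 5.0 * np.sin(2 * np.pi * 5.0 * t)
        weak_in = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        s = self.make_set([strong_out, weak_in])
        np.testing.assert_array_equal(select_imf_by_band(s), weak_in)

    def test_tie_breaks_to_first(self):
        t = np.arange(900) / self.fps
        tone = np.sin(2 * np.pi * 1.2 * t)
        s = self.make_set([tone, tone.copy()])
        assert select_imf_by_band(s) is s.imfs[0]

    def test_no_in_band_energy_errors(self):
        s = self.make_set([np.zeros(900)])
        with pytest.raises(ValueError, match="in-band"):
            select_imf_by_band(s)

    def test_eemd_then_selection_recovers_pulse_band_mode(self):
        # tone + slow drift: the selected mode is an early IMF carrying the
        # 1.2 Hz tone, with the drift relegated to later modes
        t = np.arange(900) / self.fps
        x = np.sin(2 * np.pi * 1.2 * t) + np.sin(2 * np.pi * 0.1 * t)
        imfset = eemd(x, PreprocConfig(), seed=3, fps=self.fps)
        sel = select_imf_by_band(imfset)
        f = np.fft.rfftfreq(1 << 13, 1 / self.fps)
        dom = f[np.argmax(np.abs(np.fft.rfft(sel, 1 << 13)))]
        assert dom == pytest.approx(1.2, abs=0.1)
        chosen = next(i for i, imf in enumerate(imfset.imfs) if imf is sel)
        assert chosen <= 1
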