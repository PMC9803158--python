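"""Autocorrelation periodicity scores and weighted reconstruction."""

import numpy as np
import pytest

from lassa.ealm import ealm_decompose
from lassa.selection import (
    SelectConfig,
    autocorrelation,
    max_autocorr_coefficient,
    reconstruct,
    select_components,
)
from lassa.ssa import build_trajectory, decompose


def autocorr_bruteforce(z, max_lag):
    """Literal double-loop evaluation of the biased normalized autocorrelation."""
    n = z.size
    mu = z.mean()
    var = z.var()
    out = np.zeros(max_lag + 1)
    for k in range(max_lag + 1):
        acc = 0.0
        for t in range(n - k):
            acc += (z[t] - mu) * (z[t + k] - mu)
        out[k] = acc / (n * var)
    return out


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self, rng):
        for _ in range(5):
            z = rng.normal(size=rng.integers(10, 200))
            assert autocorrelation(z, 5)[0] == 1.0

    def test_matches_bruteforce(self, rng):
        z = rng.normal(size=150)
        np.testing.assert_allclose(
            autocorrelation(z, 60), autocorr_bruteforce(z, 60), atol=1e-12
        )

    def test_sinusoid_peak_at_period(self):
        T = 30
        z = np.sin(2 * np.pi * np.arange(20 * T) / T)
        P = autocorrelation(z, 3 * T)
        assert P[T] >= 0.95
        assert P[T] >= P[T - 2] and P[T] >= P[T + 2]

    def test_white_noise_peaks_stay_small(self):
        hits = 0
        for seed in range(50):
            z = np.random.default_rng(seed).normal(size=1000)
            P = autocorrelation(z, 400)
            if np.max(P[2:]) < 0.2:
                hits += 1
        assert hits >= 49

    def test_bounded_by_one(self, rng):
        z = rng.normal(size=300)
        assert np.max(np.abs(autocorrelation(z, 250))) <= 1.0 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.full(50, 1.0), 10)


class TestMaxAutocorrCoefficient:
    def test_sinusoid_peak_value_recovered(self):
        T = 30
        z = np.sin(2 * np.pi * np.arange(600) / T)
        P = autocorrelation(z, 360)
        rho = max_autocorr_coefficient(P, SelectConfig())
        assert rho == pytest.approx(np.max(P[T - 1 : T + 2]), abs=1e-6)

    def test_monotone_decay_gives_sentinel(self):
        P = np.exp(-np.arange(100) / 10.0)
        assert max_autocorr_coefficient(P, SelectConfig()) == -1.0

    def test_scale_and_sign_invariance(self, rng):
        z = np.sin(2 * np.pi * np.arange(600) / 25) + 0.1 * rng.normal(size=600)
        cfg = SelectConfig()
        rho = max_autocorr_coefficient(autocorrelation(z, 300), cfg)
        for zz in (5.0 * z, -z):
            assert max_autocorr_coefficient(
                autocorrelation(zz, 300), cfg
            ) == pytest.approx(rho, abs=1e-12)


class TestSelectComponents:
    fps = 30.0

    def decompose_signal(self, x):
        X = build_trajectory(x, 90)
        return decompose(X), ealm_decompose(X).s

    def test_pure_sinusoid_leading_pair_selected(self):
        t = np.arange(900) / self.fps
        x = np.sin(2 * np.pi * 1.2 * t)
        dec, s = self.decompose_signal(x)
        scores = select_components(dec, max(s, 2), fps=self.fps)
        assert scores[0].selected and scores[1].selected
        xrc = reconstruct(scores)
        # reconstruction tracks the tone (weights halve the amplitude of the pair sum)
        corr = np.corrcoef(xrc, x)[0, 1]
        assert corr > 0.999

    def test_periodic_pair_passes_noise_fails(self, rng):
        t = np.arange(900) / self.fps
        x = np.sin(2 * np.pi * 1.2 * t) + 0.5 * rng.normal(size=900)
        dec, _ = self.decompose_signal(x)
        scores = select_components(dec, 12, fps=self.fps)
        assert scores[0].rho > 0.85 and scores[1].rho > 0.85
        assert min(sc.rho for sc in scores) <= 0.85

    def test_threshold_zero_selects_everything_periodic_scored(self):
        t = np.arange(900) / self.fps
        x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 2.2 * t)
        dec, _ = self.decompose_signal(x)
        cfg = SelectConfig(rho_threshold=0.0)
        scores = select_components(dec, 4, cfg, fps=self.fps)
        assert all(sc.selected for sc in scores)

    def test_monotone_threshold_property(self, rng):
        t = np.arange(900) / self.fps
        x = np.sin(2 * np.pi * 1.2 * t) + 0.4 * rng.normal(size=900)
        dec, _ = self.decompose_signal(x)
        sets = []
        for thr in (0.5, 0.7, 0.9):
            scores = select_components(dec, 10, SelectConfig(rho_threshold=thr), fps=self.fps)
            sets.append({sc.index for sc in scores if sc.rho > thr})
        assert sets[2] <= sets[1] <= sets[0]

    def test_fallback_keeps_best_component(self, rng):
        # with a threshold no component can reach, argmax-rho survives alone
        dec, _ = self.decompose_signal(rng.normal(size=600))
        scores = select_components(dec, 8, SelectConfig(rho_threshold=0.9999), fps=self.fps)
        assert sum(sc.selected for sc in scores) == 1
        best = max(scores, key=lambda sc: sc.rho)
        assert best.selected

    def test_invalid_s_rejected(self, rng):
        dec, _ = self.decompose_signal(rng.normal(size=600))
        with pytest.raises(ValueError):
            select_components(dec, 0, fps=self.fps)


class TestReconstruct:
    def make_scores(self, dec, flags, cfg=None):
        cfg = cfg or SelectConfig(rho_threshold=0.0)
        scores = select_components(dec, len(flags), cfg, fps=30.0)
        for sc, f in zip(scores, flags):
            sc.selected = f
        return scores

    def test_single_component_weight_one(self, rng):
        dec = decompose(build_trajectory(rng.normal(size=300), 30))
        scores = select_components(dec, 1, SelectConfig(rho_threshold=0.0), fps=30.0)
        assert scores[0].weight == pytest.approx(1.0)
        np.testing.assert_allclose(reconstruct(scores), scores[0].series)

    def test_weights_sum_to_one(self, rng):
        t = np.arange(900) / 30.0
        x = np.sin(2 * np.pi * 1.2 * t) + 0.2 * rng.normal(size=900)
        dec = decompose(build_trajectory(x, 90))
        scores = select_components(dec, 10, fps=30.0)
        assert sum(sc.weight for sc in scores) == pytest.approx(1.0)

    def test_equal_singular_values_average(self, rng):
        from lassa.selection import ComponentScore

        z1, z2 = rng.normal(size=(2, 100))
        scores = [
            ComponentScore(index=i, series=z, singular_value=4.0, rho=0.9,
                           selected=True, weight=0.5)
            for i, z in enumerate((z1, z2))
        ]
        np.testing.assert_allclose(reconstruct(scores), 0.5 * (z1 + z2), atol=1e-12)

    def test_weights_are_singular_value_proportions(self, rng):
        t = np.arange(900) / 30.0
        x = np.sin(2 * np.pi * 1.2 * t) + 0.3 * np.sin(2 * np.pi * 0.8 * t)
        dec = decompose(build_trajectory(x, 90))
        scores = select_components(dec, 4, SelectConfig(rho_threshold=0.0), fps=30.0)
        lam = np.array([sc.singular_value for sc in scores])
        np.testing.assert_allclose(
            [sc.weight for sc in scores], lam / lam.sum(), atol=1e-12
        )
        np.testing.assert_allclose(
            reconstruct(scores),
            sum(sc.weight * sc.series for sc in scores),
            atol=1e-12,
        )
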