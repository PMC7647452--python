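"""Wavelet decomposition, threshold rules, shrinkage and selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import catacrotic as cc
from catacrotic.denoise import (
    COMBO_ORDER,
    DenoiseConfig,
    WaveletDenoiser,
    decompose,
    estimate_sigma,
    reconstruct,
)


class TestDecomposition:
    @pytest.mark.parametrize("n", [64, 257, 1000, 4096])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.standard_normal(n)
        dec = decompose(x, DenoiseConfig())
        y = reconstruct(dec)
        assert np.linalg.norm(y - x) <= 1e-8 * np.linalg.norm(x)

    def test_constant_signal_has_vanishing_details(self):
        dec = decompose(np.full(256, 3.7), DenoiseConfig())
        for cd in dec.coeffs[1:]:
            assert np.max(np.abs(cd)) < 1e-10

    def test_band_annotation(self):
        dec = decompose(np.zeros(256), DenoiseConfig(), fs=100.0)
        assert dec.bands_hz() == [(0.0, 6.25), (6.25, 12.5), (12.5, 25.0), (25.0, 50.0)]

    def test_sine_energy_lands_in_matching_band(self):
        # 10 Hz at fs = 100 belongs to the 6.25-12.5 Hz band (cD3)
        t = np.arange(2048) / 100.0
        dec = decompose(np.sin(2 * np.pi * 10 * t), DenoiseConfig())
        energies = [np.sum(c**2) for c in dec.coeffs]  # [cA3, cD3, cD2, cD1]
        assert np.argmax(energies) == 1
        assert (energies[1] + energies[2]) > 0.8 * sum(energies)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            decompose(np.zeros(10), DenoiseConfig())


class TestThresholdValue:
    def test_zero_sigma_gives_zero_threshold(self):
        c = np.array([1.0, -2.0, 3.0])
        assert cc.threshold_value(c, "sure", 0.0) == 0.0
        assert cc.threshold_value(c, "minimax", 0.0) == 0.0

    def test_minimax_closed_form(self):
        t = cc.threshold_value(np.ones(1024), "minimax", 1.0)
        assert t == pytest.approx(0.3936 + 0.1829 * 10.0, abs=1e-12)

    def test_minimax_zero_for_short_vectors(self):
        assert cc.threshold_value(np.ones(32), "minimax", 1.0) == 0.0

    def test_minimax_scales_linearly_with_sigma(self):
        c = np.ones(1024)
        t1 = cc.threshold_value(c, "minimax", 0.5)
        t2 = cc.threshold_value(c, "minimax", 2.0)
        assert t2 == pytest.approx(4.0 * t1)

    def test_sure_keeps_isolated_large_coefficient(self):
        c = np.zeros(64)
        c[-1] = 100.0
        t = cc.threshold_value(c, "sure", 1.0)
        assert t < 100.0

    def test_sure_matches_direct_risk_minimization(self, rng):
        # independent oracle: evaluate SURE at every candidate directly
        for _ in range(20):
            c = rng.standard_normal(rng.integers(8, 200)) * rng.uniform(0.5, 3)
            sigma = rng.uniform(0.2, 2.0)
            a = np.abs(c / sigma)
            best_t, best_risk = None, np.inf
            for t in np.sort(a):
                risk = (a.size - 2 * np.sum(a <= t)
                        + np.sum(np.minimum(a, t) ** 2))
                if risk < best_risk:
                    best_risk, best_t = risk, t
            assert cc.threshold_value(c, "sure", sigma) == pytest.approx(sigma * best_t)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cc.threshold_value(np.array([]), "sure", 1.0)
        with pytest.raises(ValueError):
            cc.threshold_value(np.ones(4), "unknown", 1.0)


class TestApplyThreshold:
    def test_definitions(self):
        c = np.array([3.0, -1.0, 0.5])
        np.testing.assert_array_equal(cc.apply_threshold(c, 0.0, "hard"), c)
        np.testing.assert_array_equal(cc.apply_threshold(c, 0.0, "soft"), c)
        np.testing.assert_array_equal(cc.apply_threshold(c, 1.0, "hard"), [3.0, 0.0, 0.0])
        np.testing.assert_array_equal(cc.apply_threshold(c, 1.0, "soft"), [2.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(0, 50),
    )
    def test_soft_is_a_contraction_and_hard_preserves_survivors(self, values, t):
        c = np.asarray(values)
        soft = cc.apply_threshold(c, t, "soft")
        hard = cc.apply_threshold(c, t, "hard")
        assert np.max(np.abs(soft), initial=0.0) <= np.max(np.abs(c), initial=0.0)
        survivors = np.abs(c) > t
        np.testing.assert_array_equal(hard[survivors], c[survivors])
        assert np.all(hard[~survivors] == 0)


class TestScores:
    def test_identical_signals(self):
        x = np.sin(np.arange(100.0))
        assert cc.rmse(x, x) == 0.0
        assert cc.snr_db(x, x) == np.inf

    def test_constant_offset_rmse(self):
        x = np.tile([0.0, 1.0], 50)
        assert cc.rmse(x, x + 0.1) == pytest.approx(0.1)

    def test_snr_of_known_noise_level(self, rng):
        t = np.arange(20000) / 100.0
        x = np.sqrt(2.0) * np.sin(2 * np.pi * t)  # unit variance
        y = x + rng.standard_normal(t.size) * 0.1
        assert cc.snr_db(x, y) == pytest.approx(20.0, abs=1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cc.snr_db(np.zeros(5), np.zeros(6))
        with pytest.raises(ValueError):
            cc.rmse(np.zeros(5), np.zeros(6))


class TestSelectAndDenoise:
    def test_improves_noisy_ppg(self):
        record, _ = cc.simulate_record(
            noise=cc.NoiseParams(white_snr_db=10, wander_amplitude=0.0), seed=2)
        denoised, report = cc.select_and_denoise(record.signal, record.clean)
        assert len(report.scores) == 4
        out_snr = report.scores[report.chosen]["snr_db"]
        assert out_snr > report.input_snr_db
        assert out_snr == max(s["snr_db"] for s in report.scores.values())

    def test_singleton_grid_is_chosen(self):
        record, _ = cc.simulate_record(seed=2)
        _, report = cc.select_and_denoise(
            record.signal, record.clean, grid=[("minimax", "hard")])
        assert report.chosen == ("minimax", "hard")

    def test_without_reference_uses_configured_combination(self):
        record, _ = cc.simulate_record(seed=2)
        config = DenoiseConfig(rule="minimax", mode="soft")
        _, report = cc.select_and_denoise(record.signal, None, config)
        assert report.chosen == ("minimax", "soft")
        assert not report.reference_used
        assert set(report.thresholds) == {"sure", "minimax"}
        assert all(len(v) == 3 for v in report.thresholds.values())

    def test_reference_length_checked(self):
        with pytest.raises(ValueError):
            cc.select_and_denoise(np.zeros(256), np.zeros(128))

    def test_combo_order_is_the_documented_tie_break(self):
        assert COMBO_ORDER == (("sure", "soft"), ("sure", "hard"),
                               ("minimax", "soft"), ("minimax", "hard"))


class TestWaveletDenoiserEstimator:
    def test_fit_transform_roundtrip(self):
        record, _ = cc.simulate_record(
            noise=cc.NoiseParams(white_snr_db=15, wander_amplitude=0.0), seed=5)
        est = WaveletDenoiser()
        out = est.fit_transform(record.signal)
        assert est.sigma_ > 0 and len(est.thresholds_) == 3
        assert cc.snr_db(record.clean, out) > cc.snr_db(record.clean, record.signal)

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = WaveletDenoiser(rule="minimax", mode="hard")
        params = est.get_params()
        assert params["rule"] == "minimax"
        cloned = clone(est)
        assert cloned.get_params() == params
        with pytest.raises(AttributeError):
            cloned.transform(np.zeros(256))

    def test_sigma_estimate_tracks_noise_level(self, rng):
        x = rng.standard_normal(4096) * 0.5
        dec = decompose(x, DenoiseConfig())
        assert estimate_sigma(dec) == pytest.approx(0.5, rel=0.15)
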