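"""Detector primitives against hand evaluation and brute-force oracles;
whole-detector sensitivity against simulator ground truth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgfuse as ef
from ecgfuse.qrs import (
    compute_thresholds,
    derivative_filter,
    detect_r_peaks,
    moving_window_integrate,
    segment_beats,
    square,
)
from ecgfuse.types import RawECG


def bf_derivative(x):
    """Independent loop evaluation of the 5-tap stencil, edge-replicated."""
    n = x.size
    y = np.empty(n)
    for i in range(n):
        xm2 = x[max(i - 2, 0)]
        xm1 = x[max(i - 1, 0)]
        xp1 = x[min(i + 1, n - 1)]
        xp2 = x[min(i + 2, n - 1)]
        y[i] = (2 * (xp1 - xm1) + (xp2 - xm2)) / 8.0
    return y


class TestDerivativeFilter:
    def test_constant_gives_zero(self):
        np.testing.assert_allclose(derivative_filter(np.full(20, 4.2)), 0.0)

    def test_unit_ramp_gives_one_interior(self):
        y = derivative_filter(np.arange(30, dtype=float))
        np.testing.assert_allclose(y[2:-2], 1.0)

    def test_impulse_matches_hand_evaluation(self):
        x = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        np.testing.assert_allclose(derivative_filter(x), bf_derivative(x))

    def test_random_matches_bruteforce(self):
        x = np.random.default_rng(0).normal(size=100)
        np.testing.assert_allclose(derivative_filter(x), bf_derivative(x), atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            derivative_filter(np.zeros(4))


class TestSquareAndIntegrate:
    def test_square(self):
        np.testing.assert_array_equal(square(np.array([-2.0, 3.0])), [4.0, 9.0])

    def test_constant_mean_after_warmup(self):
        y = moving_window_integrate(np.full(50, 2.5), 10)
        np.testing.assert_allclose(y, 2.5)

    def test_impulse_plateau(self):
        x = np.zeros(20)
        x[8] = 1.0
        y = moving_window_integrate(x, 4)
        np.testing.assert_allclose(y[8:12], 0.25)
        assert y[12] == 0.0

    def test_matches_bruteforce_windowed_mean(self):
        x = np.random.default_rng(1).normal(size=60)
        got = moving_window_integrate(x, 7)
        expected = np.array([x[max(0, i - 6): i + 1].mean() for i in range(60)])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            moving_window_integrate(np.zeros(5), 0)
        with pytest.raises(ValueError):
            moving_window_integrate(np.zeros(5), 6)


class TestThresholds:
    @pytest.mark.parametrize(
        "spki,npki,expected",
        [
            (1.0, 0.2, (0.4, 0.2)),
            (0.7, 0.7, (0.7, 0.35)),
            (0.8, 0.0, (0.2, 0.1)),
        ],
    )
    def test_threshold_formula(self, spki, npki, expected):
        th1, th2 = compute_thresholds(spki, npki)
        assert th1 == pytest.approx(expected[0])
        assert th2 == pytest.approx(expected[1])
        assert th2 == pytest.approx(0.5 * th1)

    def test_corrupt_state_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(0.1, 0.5)


class TestDetector:
    def test_zero_noise_sensitivity_and_ppv_one(self):
        rec = ef.generate_record(
            30, class_mix={c: 0.2 for c in ef.CLASSES},
            noise=ef.NoiseSpec.none(), rng_seed=0,
        )
        det = detect_r_peaks(ef.preprocess(rec.signal))
        tr = rec.true_r_indices
        sens = np.mean([np.min(np.abs(det - t)) <= 2 for t in tr])
        ppv = np.mean([np.min(np.abs(tr - d)) <= 2 for d in det])
        assert sens == 1.0
        assert ppv == 1.0

    def test_default_noise_sensitivity(self):
        rec = ef.generate_record(
            200, class_mix={c: 0.2 for c in ef.CLASSES}, rng_seed=1
        )
        det = detect_r_peaks(ef.preprocess(rec.signal))
        sens = np.mean([np.min(np.abs(det - t)) <= 10 for t in rec.true_r_indices])
        assert sens >= 0.99

    def test_flat_signal_yields_nothing(self):
        assert detect_r_peaks(RawECG(np.zeros(1000), fs=360)).size == 0

    def test_strictly_increasing_with_refractory_gaps(self):
        rec = ef.generate_record(100, class_mix={c: 0.2 for c in ef.CLASSES}, rng_seed=2)
        det = detect_r_peaks(ef.preprocess(rec.signal))
        gaps = np.diff(det)
        assert np.all(gaps > 0)
        assert np.all(gaps >= int(0.2 * rec.signal.fs))

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_amplitude_scale_invariance(self, scale):
        rec = ef.generate_record(20, rng_seed=3)
        sig = ef.preprocess(rec.signal)
        base = detect_r_peaks(sig)
        scaled = detect_r_peaks(RawECG(sig.samples * scale, fs=sig.fs))
        np.testing.assert_array_equal(base, scaled)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(RawECG(np.zeros(100), fs=360))


class TestSegmentation:
    def test_windows_centered_on_r(self):
        rec = ef.generate_record(10, noise=ef.NoiseSpec.none(), rng_seed=0)
        segments, skipped = segment_beats(rec.signal, rec.true_r_indices)
        assert skipped == 0
        for seg in segments:
            assert seg.samples.shape == (250,)
            assert int(np.argmax(np.abs(seg.samples))) == 99

    def test_edge_beats_skipped(self):
        sig = RawECG(np.zeros(10000), fs=360)
        segments, skipped = segment_beats(sig, np.array([50]))
        assert segments == [] and skipped == 1

    def test_skip_count_near_both_edges(self):
        sig = RawECG(np.zeros(10000), fs=360)
        r = np.concatenate(([40], np.arange(500, 9000, 300), [9900]))
        segments, skipped = segment_beats(sig, r)
        assert skipped == 2
        assert len(segments) == r.size - 2
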