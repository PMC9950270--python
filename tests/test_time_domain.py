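"""Kinematics, force, smoothness and tilt indicator computations."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from spiralpen.indicators import time_domain as td
from spiralpen.preprocess import StrokeSegmentation

from oracles import extrema_scan

FS = 50.0


def _seg(intervals, n):
    mask = np.zeros(n, bool)
    for a, b in intervals:
        mask[a:b] = True
    return StrokeSegmentation(len(intervals), max(len(intervals) - 1, 0),
                              intervals, mask)


class TestExecutionTime:
    def test_single_stroke(self):
        assert td.execution_time(_seg([(0, 500)], 500), FS) == 10.0

    def test_lift_time_included_in_span(self):
        assert td.execution_time(_seg([(0, 100), (200, 300)], 300), FS) == 6.0

    def test_no_strokes_missing(self):
        assert np.isnan(td.execution_time(_seg([], 10), FS))


class TestConsPeakDiff:
    def test_pure_sinusoid_equal_swings(self):
        t = np.arange(500) / FS
        avg, cv = td.cons_peak_diff(3.0 * np.sin(2 * np.pi * 2 * t))
        assert avg == pytest.approx(6.0, rel=0.01)
        assert cv == pytest.approx(0.0, abs=0.01)

    def test_hand_computed_extrema_sequence(self):
        # extrema values 1, -1, 2, -2 -> swings [2, 3, 4]
        x = np.concatenate([
            np.linspace(0, 1, 10), np.linspace(1, -1, 10),
            np.linspace(-1, 2, 10), np.linspace(2, -2, 10),
            np.linspace(-2, 0, 10)])
        avg, cv = td.cons_peak_diff(x)
        assert avg == pytest.approx(3.0, abs=1e-9)
        assert cv == pytest.approx(np.std([2, 3, 4]) / 3.0, abs=1e-9)

    def test_monotone_ramp_missing(self):
        avg, cv = td.cons_peak_diff(np.linspace(0, 1, 100))
        assert np.isnan(avg) and np.isnan(cv)


class TestForceStats:
    def test_constant_force(self):
        assert td.force_stats(np.full(100, 5.0)) == (5.0, 0.0, 0.0)

    def test_overshoot_is_max_minus_median(self):
        f = np.array([1, 2, 3, 4, 100] * 2, float)
        _, _, ovs = td.force_stats(f)
        assert ovs == 100 - np.median(f)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            td.force_stats(np.array([2.0, 4.0]))


class TestRateOfChanges:
    def test_three_hz_sinusoid(self):
        t = np.arange(int(10 * FS)) / FS
        rate = td.rate_of_changes(np.sin(2 * np.pi * 3 * t), FS)
        assert rate == pytest.approx(6.0, abs=0.1)

    def test_constant_series(self):
        assert td.rate_of_changes(np.full(200, 3.3), FS) == 0.0

    def test_prominence_guard_resists_small_noise(self, rng):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 5 * t) + 0.01 * rng.normal(size=t.size)
        assert td.rate_of_changes(x, FS) == pytest.approx(10.0, abs=0.5)


@pytest.mark.parametrize("seed", range(8))
def test_extrema_match_exhaustive_scan(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(50, 1000))
    x = np.cumsum(r.normal(size=n))  # smooth-ish random walk
    assert list(td.find_extrema(x)) == extrema_scan(x)


class TestSparc:
    def test_extra_tone_lowers_smoothness(self):
        t = np.arange(int(20 * FS)) / FS
        a = np.sin(2 * np.pi * 3 * t)
        b = a + np.sin(2 * np.pi * 9 * t)
        assert td.sparc(a, FS) > td.sparc(b, FS)

    def test_threshold_monotonicity(self, rng):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 4 * t) + 0.3 * rng.normal(size=t.size)
        assert td.sparc(x, FS, 50) >= td.sparc(x, FS, 10)

    def test_noise_less_smooth_than_tone(self, rng):
        t = np.arange(int(20 * FS)) / FS
        tone = np.sin(2 * np.pi * 4 * t)
        noise = rng.normal(0, np.sqrt(0.5), t.size)
        assert td.sparc(noise, FS) < td.sparc(tone, FS)

    def test_all_zero_missing(self):
        assert np.isnan(td.sparc(np.zeros(1000), FS))


class TestLdlj:
    def test_analytic_value_for_sinusoid(self):
        f, T = 5.0, 10.0
        t = np.arange(int(T * FS)) / FS
        x = 2.5 * np.sin(2 * np.pi * f * t)
        expected = -np.log((2 * np.pi * f) ** 2 * T ** 2 / 2)
        assert td.ldlj(x, FS) == pytest.approx(expected, abs=0.2)

    def test_amplitude_invariance(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 4 * t)
        assert td.ldlj(x, FS) == pytest.approx(td.ldlj(7.3 * x, FS), abs=1e-9)

    def test_zero_peak_missing(self):
        assert np.isnan(td.ldlj(np.zeros(200), FS))


def test_ripple_sweep_degrades_both_smoothness_metrics():
    t = np.arange(int(20 * FS)) / FS
    carrier = np.sin(2 * np.pi * 1 * t)
    amps = [0.0, 0.15, 0.3, 0.5, 0.7, 0.9]
    sparcs, ldljs = [], []
    for a in amps:
        x = carrier + a * np.sin(2 * np.pi * 9 * t)
        sparcs.append(td.sparc(x, FS))
        ldljs.append(td.ldlj(x, FS))
    assert spearmanr(amps, sparcs)[0] == -1.0
    assert spearmanr(amps, ldljs)[0] == -1.0


class TestTiltStats:
    def test_constant(self):
        assert td.tilt_stats(np.full(100, 45.0)) == (45.0, 0.0, 0.0)

    def test_two_level(self):
        mean, var, cv = td.tilt_stats(np.array([30.0, 60.0] * 5))
        assert (mean, var) == (45.0, 225.0)
        assert cv == pytest.approx(1 / 3, abs=1e-9)

    def test_zero_mean_cv_guarded(self):
        _, _, cv = td.tilt_stats(np.array([-1.0, 1.0] * 5))
        assert np.isnan(cv)


@pytest.mark.parametrize("scale", [0.5, 3.0, 1000.0])
def test_cv_indicators_scale_invariant(scale, rng):
    x = np.abs(rng.normal(5, 1, 400)) + 1
    _, cv1 = td.cons_peak_diff(x)
    _, cv2 = td.cons_peak_diff(scale * x)
    if not np.isnan(cv1):
        assert cv2 == pytest.approx(cv1, rel=1e-9)
    _, fcv1, _ = td.force_stats(x)
    _, fcv2, _ = td.force_stats(scale * x)
    assert fcv2 == pytest.approx(fcv1, rel=1e-9)
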