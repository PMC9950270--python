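"""Welch spectra, relative band powers and amplitude indicators."""

import numpy as np
import pytest

from spiralpen.emd import TremorComponent
from spiralpen.exceptions import TooShortError
from spiralpen.indicators import spectral as spc

from oracles import welch_band_power_bruteforce

FS = 50.0


def _tone(freq, dur=60.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestWelchPsd:
    def test_tone_located_on_grid(self):
        spec = spc.welch_psd(_tone(5.0), FS)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(5.0, abs=0.1)
        assert np.diff(spec.freqs)[0] == pytest.approx(0.1, abs=1e-9)

    def test_parseval_for_tone(self):
        spec = spc.welch_psd(_tone(5.0), FS)
        assert spc.total_power(spec) == pytest.approx(0.5, rel=0.1)

    def test_parseval_for_white_noise(self, rng):
        x = rng.normal(0, 1, int(120 * FS))
        spec = spc.welch_psd(x, FS)
        assert spc.total_power(spec) == pytest.approx(np.var(x), rel=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            spc.welch_psd(np.zeros(100), FS)

    @pytest.mark.parametrize("band", [(0, 2), (2, 4), (4, 7), (8, 12)])
    def test_band_power_matches_bruteforce(self, band, rng):
        x = _tone(5.0) + 0.5 * rng.normal(size=int(60 * FS))
        spec = spc.welch_psd(x, FS)
        ours = spc.band_power(spec, *band)
        ref = welch_band_power_bruteforce(x, FS, *band)
        assert ours == pytest.approx(ref, rel=0.05)


class TestRelativeBandPower:
    def test_pure_tone_band_allocation(self):
        spec = spc.welch_psd(_tone(5.0), FS)
        assert spc.relative_band_power(spec, (4, 7)) >= 0.95
        assert spc.relative_band_power(spec, (0, 2)) <= 0.02

    def test_equal_tones_split_evenly(self):
        spec = spc.welch_psd(_tone(1.0) + _tone(5.0, phase=1.0), FS)
        assert spc.relative_band_power(spec, (0, 2)) == pytest.approx(0.5, abs=0.05)
        assert spc.relative_band_power(spec, (4, 7)) == pytest.approx(0.5, abs=0.05)

    def test_fractions_valid_and_subnormalized(self, rng):
        x = rng.normal(0, 1, int(30 * FS))
        spec = spc.welch_psd(x, FS)
        fracs = [spc.relative_band_power(spec, b) for b in spc.RPW_BANDS]
        assert all(0 <= f <= 1 for f in fracs)
        assert sum(fracs) <= 1.0


class TestPeakBandPower:
    def test_pure_tone_concentrated(self):
        spec = spc.welch_psd(_tone(5.0), FS)
        assert spc.rpw_peak_band(spec) >= 0.9

    def test_white_noise_flat_share(self, rng):
        x = rng.normal(0, 1, int(120 * FS))
        spec = spc.welch_psd(x, FS)
        expected = 2.0 / (FS / 2)
        assert spc.rpw_peak_band(spec) == pytest.approx(expected, abs=0.05)

    def test_two_separated_tones_half_share(self):
        spec = spc.welch_psd(_tone(4.0) + _tone(10.0, phase=0.7), FS)
        assert spc.rpw_peak_band(spec) == pytest.approx(0.5, abs=0.05)


def _tremor(series, peak, fs=FS):
    return TremorComponent(tremor=series, residual=np.zeros_like(series),
                           imf_table=[], peak_freq=peak, fs=fs)


class TestMeanHarmonicPower:
    def test_doubling_amplitude_adds_ln4(self):
        x = _tone(5.0, dur=30)
        a = spc.mean_harmonic_power(_tremor(x, 5.0))
        b = spc.mean_harmonic_power(_tremor(2 * x, 5.0))
        assert b - a == pytest.approx(np.log(4), abs=0.1)

    def test_frequency_shift_invariance(self):
        a = spc.mean_harmonic_power(_tremor(_tone(4.0, dur=30), 4.0))
        b = spc.mean_harmonic_power(_tremor(_tone(6.0, dur=30), 6.0))
        assert a == pytest.approx(b, abs=0.1)

    def test_undefined_peak_missing(self):
        x = np.zeros(1500)
        assert np.isnan(spc.mean_harmonic_power(_tremor(x, float("nan"))))


class TestWindowedRms:
    def test_constant_series(self):
        assert spc.windowed_rms(np.full(1500, -3.0), FS, 10.0) == pytest.approx(3.0)

    def test_sinusoid_rms(self):
        assert spc.windowed_rms(_tone(5.0, amp=2.0), FS, 10.0) == pytest.approx(
            2.0 / np.sqrt(2), rel=0.02)

    def test_burst_max_exceeds_mean(self):
        x = _tone(5.0, dur=30)
        x[:500] *= 5  # burst in the first 10 s
        assert (spc.windowed_rms(x, FS, 1.0, reduce="max")
                > spc.windowed_rms(x, FS, 1.0, reduce="mean"))


class TestSnrTremor:
    def test_pure_tone_high_snr(self):
        assert spc.snr_tremor(_tremor(_tone(5.0, dur=30), 5.0)) > 20

    def test_equal_power_split_near_unity(self):
        x = _tone(5.0, dur=60) + _tone(9.0, dur=60, phase=0.3)
        assert spc.snr_tremor(_tremor(x, 5.0)) == pytest.approx(1.0, rel=0.2)

    def test_undefined_peak_missing(self):
        assert np.isnan(spc.snr_tremor(_tremor(np.zeros(1500), float("nan"))))


class TestOutlierLevel:
    def test_flat_spectrum_guarded(self):
        spec = spc.SpectralEstimate(np.linspace(0, 25, 251), np.ones(251), FS)
        lev, amp = spc.outlier_level(spec)
        assert np.isnan(lev) and np.isnan(amp)

    def test_hand_computed_peak_z_score(self):
        freqs = np.linspace(2, 12, 100)
        psd = np.ones(100)
        psd[40] = 101.0
        spec = spc.SpectralEstimate(freqs, psd, FS)
        lev, amp = spc.outlier_level(spec)
        assert lev == pytest.approx((101 - 2) / np.std(psd), rel=1e-9)
        assert amp == pytest.approx(lev * 101, rel=1e-9)

    def test_sharper_peak_larger_outlier_level(self, rng):
        levs = []
        for width in (3.0, 1.5, 0.8, 0.4, 0.2):
            freqs = np.linspace(2, 12, 101)
            psd = np.exp(-0.5 * ((freqs - 6) / width) ** 2) + 0.01
            lev, _ = spc.outlier_level(spc.SpectralEstimate(freqs, psd, FS))
            levs.append(lev)
        assert all(b > a for a, b in zip(levs, levs[1:]))
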