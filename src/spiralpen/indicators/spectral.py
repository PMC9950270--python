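"""Frequency- and amplitude-domain indicators on a shared Welch estimator.

All spectra are one-sided Welch estimates with a Hann taper, 500-sample
(10 s) segments, 50% overlap and a 0.1 Hz grid.  The frequency-domain
indicators (relative band powers, outlier levels) are computed on the raw
mean-removed norms rather than the 2-12 Hz band-passed ones, so that the
sub-2 Hz drawing oscillation keeps its share of the total power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from ..emd import TremorComponent
from ..exceptions import TooShortError
from ..preprocess import bandpass

WELCH_WINDOW_LEN = 500
WELCH_OVERLAP = 0.5
WELCH_GRID_HZ = 0.1

RPW_BANDS = ((0.0, 2.0), (2.0, 4.0), (4.0, 7.0), (8.0, 12.0))
PEAK_SEARCH_BAND = (2.0, 12.0)
#: half-width in Hz of the "interval around the spectral peak"
PEAK_HALFWIDTH_HZ = 1.0

MM_PER_M = 1000.0


@dataclass
class SpectralEstimate:
    """One-sided Welch PSD with its estimation parameters."""

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    window_len: int = WELCH_WINDOW_LEN
    overlap: float = WELCH_OVERLAP
    whole_series: bool = False  # True when the series was shorter than one window


def welch_psd(x: np.ndarray, fs: float) -> SpectralEstimate:
    """Welch PSD: Hann window, 500-sample segments, 50% overlap, 0.1 Hz grid."""
    x = np.asarray(x, dtype=float)
    if x.size < WELCH_WINDOW_LEN // 2:
        raise TooShortError("too short for PSD (need at least 250 samples)")
    nperseg = min(WELCH_WINDOW_LEN, x.size)
    nfft = max(nperseg, int(round(fs / WELCH_GRID_HZ)))
    f, p = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=int(nperseg * WELCH_OVERLAP), nfft=nfft)
    return SpectralEstimate(f, p, fs, nperseg, WELCH_OVERLAP,
                            whole_series=x.size < WELCH_WINDOW_LEN)


def band_power(spec: SpectralEstimate, lo: float, hi: float) -> float:
    """Trapezoid-integrated power over the half-open band ``[lo, hi)``."""
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[sel], spec.freqs[sel]))


def total_power(spec: SpectralEstimate) -> float:
    return float(np.trapezoid(spec.psd, spec.freqs))


def relative_band_power(spec: SpectralEstimate, band: tuple[float, float]) -> float:
    """Band power divided by total power over [0, fs/2]."""
    tot = total_power(spec)
    if tot <= 0:
        return float("nan")
    return band_power(spec, *band) / tot


def spectral_peak(spec: SpectralEstimate,
                  band: tuple[float, float] = PEAK_SEARCH_BAND) -> float:
    """Frequency of the PSD maximum restricted to ``band`` (NaN if empty)."""
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not sel.any() or not np.any(spec.psd[sel] > 0):
        return float("nan")
    return float(spec.freqs[sel][np.argmax(spec.psd[sel])])


def rpw_peak_band(spec: SpectralEstimate,
                  halfwidth: float = PEAK_HALFWIDTH_HZ) -> float:
    """Relative power in a +/- ``halfwidth`` interval around the 2-12 Hz peak."""
    f_peak = spectral_peak(spec)
    if not np.isfinite(f_peak):
        return float("nan")
    tot = total_power(spec)
    if tot <= 0:
        return float("nan")
    return band_power(spec, f_peak - halfwidth, f_peak + halfwidth) / tot


def mean_harmonic_power(trem: TremorComponent,
                        halfwidth: float = PEAK_HALFWIDTH_HZ) -> float:
    """Natural log of the mean tremor PSD density around the tremor peak.

    The tremor acceleration is expressed in mm/s^2 so the log argument
    matches the scale the indicator is conventionally reported in.
    """
    if not trem.defined:
        return float("nan")
    spec = welch_psd(trem.tremor * MM_PER_M, trem.fs)
    sel = (spec.freqs >= trem.peak_freq - halfwidth) & (spec.freqs <= trem.peak_freq + halfwidth)
    mean_density = float(np.mean(spec.psd[sel]))
    if mean_density <= 0:
        return float("nan")
    return float(np.log(mean_density))


def windowed_rms(x: np.ndarray, fs: float, win_s: float, reduce: str = "mean",
                 smooth_windows: int = 1) -> float:
    """RMS over non-overlapping windows, reduced by mean or max.

    With ``reduce="max"`` a ``smooth_windows``-point moving average is
    applied to the per-window RMS values before taking the maximum.  A
    series shorter than one window falls back to a single whole-series
    window.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(win_s * fs))
    if x.size < win:
        win = x.size  # single-window fallback
    n_win = x.size // win
    vals = np.sqrt(np.mean(x[: n_win * win].reshape(n_win, win) ** 2, axis=1))
    if reduce == "mean":
        return float(np.mean(vals))
    if reduce == "max":
        if smooth_windows > 1 and vals.size >= smooth_windows:
            kernel = np.ones(smooth_windows) / smooth_windows
            vals = np.convolve(vals, kernel, mode="valid")
        return float(np.max(vals))
    raise ValueError(f"unknown reduce {reduce!r}")


def rms_filt_max(x: np.ndarray, fs: float, f_peak: float,
                 halfwidth: float = PEAK_HALFWIDTH_HZ) -> float:
    """Max of smoothed 1-s window RMS of ``x`` band-passed around ``f_peak``."""
    if not np.isfinite(f_peak):
        return float("nan")
    lo = max(f_peak - halfwidth, 0.1)
    hi = min(f_peak + halfwidth, fs / 2 - 0.1)
    filtered = bandpass(x, fs, lo, hi)
    return windowed_rms(filtered, fs, 1.0, reduce="max", smooth_windows=3)


def snr_tremor(trem: TremorComponent,
               halfwidth: float = PEAK_HALFWIDTH_HZ) -> float:
    """Power ratio of the peak-band tremor to the remaining tremor signal."""
    if not trem.defined:
        return float("nan")
    lo = max(trem.peak_freq - halfwidth, 0.1)
    hi = min(trem.peak_freq + halfwidth, trem.fs / 2 - 0.1)
    inband = bandpass(trem.tremor, trem.fs, lo, hi)
    noise = trem.tremor - inband
    p_noise = float(np.mean(noise ** 2))
    if p_noise <= 0:
        return float("nan")
    return float(np.mean(inband ** 2)) / p_noise


def outlier_level(spec: SpectralEstimate,
                  band: tuple[float, float] = PEAK_SEARCH_BAND) -> tuple[float, float]:
    """Relative outlier level of the 2-12 Hz PSD and its amplitude product.

    ``Out_Lev_Rel = (max - mean) / std`` over the band grid (a z-score of
    the peak against the band's density distribution); ``AmpXOut_Lev``
    multiplies it by the peak density.
    """
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    p = spec.psd[sel]
    if p.size == 0:
        return float("nan"), float("nan")
    std = float(np.std(p))
    if std == 0:
        return float("nan"), float("nan")
    out = (float(np.max(p)) - float(np.mean(p))) / std
    return out, out * float(np.max(p))
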