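"""Empirical mode decomposition and tremor extraction.

The tremor contribution (the "_T" signal behind the regularity and several
amplitude/frequency indicators) is isolated from the mean-removed
acceleration norm by EMD: the signal is sifted into intrinsic mode functions
(IMFs) and the tremor is the sum of the IMFs whose dominant frequency lies
in the 2-12 Hz kinematic band.

The decomposition is the classic Huang sifting scheme: cubic-spline upper
and lower envelopes through the local extrema (mirror-extended at the
boundaries), iterated until the standard-deviation stopping criterion drops
below 0.2 or 50 sift iterations are reached.  Given these fixed parameters
the decomposition is fully deterministic, and by construction the IMFs plus
the final residue reconstruct the input exactly (floating-point error only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .exceptions import TooShortError

SD_STOP = 0.2
MAX_SIFTS = 50
MAX_IMFS = 10
TREMOR_BAND_HZ = (2.0, 12.0)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau -> first sample)."""
    d = np.diff(x)
    # carry the previous non-zero sign across plateaus so a flat top counts
    # once, at its first sample
    sign = np.sign(d)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    sc = np.diff(sign)
    maxima = np.where(sc < 0)[0] + 1
    minima = np.where(sc > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    n = x.size
    k = min(2, ext.size)
    left = (-ext[:k])[::-1]
    right = (2 * (n - 1) - ext[-k:])[::-1]
    xs = np.concatenate([left, ext, right])
    ys = np.concatenate([x[ext[:k]][::-1], x[ext], x[ext[-k:]][::-1]])
    # mirroring can duplicate a knot when an extremum sits on the boundary
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    if xs.size < 2:
        return np.full(n, ys[0])
    if xs.size < 4:
        return np.interp(np.arange(n), xs, ys)
    return CubicSpline(xs, ys)(np.arange(n))


def _sift(x: np.ndarray) -> np.ndarray | None:
    """Extract one IMF from ``x``; ``None`` if ``x`` has too few extrema."""
    h = x
    for _ in range(MAX_SIFTS):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < SD_STOP:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = MAX_IMFS) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``x`` into IMFs and a residue.

    Returns
    -------
    imfs : ndarray, shape (k, n)
    residue : ndarray, shape (n,)
        ``imfs.sum(axis=0) + residue == x`` to floating-point precision.
    """
    x = np.asarray(x, dtype=float)
    imfs: list[np.ndarray] = []
    r = x.copy()
    while len(imfs) < max_imfs:
        imf = _sift(r)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
        maxima, minima = _local_extrema(r)
        if maxima.size + minima.size < 4:
            break
    return np.array(imfs).reshape(len(imfs), x.size), r


def _dominant_freq(x: np.ndarray, fs: float) -> float:
    nperseg = min(500, x.size)
    nfft = max(nperseg, int(round(fs / 0.1)))
    f, p = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, nfft=nfft)
    return float(f[np.argmax(p)])


@dataclass
class TremorComponent:
    """EMD-derived tremor series for one trial.

    ``tremor + residual`` reconstructs the input signal; ``peak_freq`` is
    the dominant tremor frequency in Hz, NaN when no IMF fell in the tremor
    band (downstream "_T" indicators are then missing).
    """

    tremor: np.ndarray
    residual: np.ndarray
    imf_table: list[tuple[float, float]]  # (dominant freq Hz, variance fraction)
    peak_freq: float
    fs: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.peak_freq)


def extract_tremor(acc_mag_raw: np.ndarray, fs: float,
                   band: tuple[float, float] = TREMOR_BAND_HZ) -> TremorComponent:
    """Isolate the tremor contribution of the acceleration norm.

    IMFs whose dominant Welch-PSD frequency lies in ``band`` are summed into
    the tremor series; everything else (including the EMD residue) is the
    residual.
    """
    x = np.asarray(acc_mag_raw, dtype=float)
    if x.size < 4 * fs:
        raise TooShortError("need at least 4 s of signal for tremor extraction")
    imfs, residue = emd(x)
    total_var = float(np.var(x)) or 1.0
    table = []
    in_band = np.zeros(len(imfs), dtype=bool)
    for k, imf in enumerate(imfs):
        fdom = _dominant_freq(imf, fs)
        table.append((fdom, float(np.var(imf)) / total_var))
        in_band[k] = band[0] <= fdom <= band[1]
    if in_band.any():
        tremor = imfs[in_band].sum(axis=0)
    else:
        tremor = np.zeros_like(x)
    residual = x - tremor
    if in_band.any() and np.any(tremor != 0):
        peak = _dominant_freq(tremor, fs)
        peak_freq = peak if 0.0 < peak < fs / 2 else float("nan")
    else:
        peak_freq = float("nan")
    return TremorComponent(tremor, residual, table, peak_freq, fs)
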