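"""Regularity-domain indicators on the EMD tremor component.

Approximate entropy and the recurrence measures quantify how repetitive the
tremor waveform is; the tremor stability index measures the dispersion of
cycle-to-cycle frequency changes; the angular-velocity change rate captures
the sharpest sustained gyro fluctuation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..preprocess import bandpass

APEN_M = 2
APEN_R_FRAC = 0.2

RQA_DIM = 3
RQA_MAX_DELAY = 10
RQA_EPS_FRAC = 0.2
RQA_MIN_LINE = 2
RQA_MAX_SAMPLES = 2000

TSI_BAND_HZ = (2.0, 12.0)
TSI_MIN_CYCLES = 10


def approximate_entropy(x: np.ndarray, m: int = APEN_M, r: float | None = None) -> float:
    """ApEn(m, r) with Chebyshev distance and self-matches included.

    ``r`` defaults to ``0.2 x std(x)``.  A constant series has entropy 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for ApEn")
    if r is None:
        r = APEN_R_FRAC * float(np.std(x))

    # Chebyshev template distances built incrementally from the scalar
    # distance matrix: D_m[i, j] = max_{k<m} |x[i+k] - x[j+k]|
    d1 = np.abs(x[:, None] - x[None, :])
    dm = d1
    for k in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d1[k:, k:])

    def phi(dmat: np.ndarray) -> float:
        counts = np.count_nonzero(dmat <= r, axis=1)
        return float(np.mean(np.log(counts / dmat.shape[0])))

    dm1 = np.maximum(dm[:-1, :-1], d1[m:, m:])
    return phi(dm) - phi(dm1)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n_vec = x.size - (dim - 1) * delay
    return np.column_stack([x[k * delay: k * delay + n_vec] for k in range(dim)])


def _autocorr_zero_delay(x: np.ndarray, cap: int = RQA_MAX_DELAY) -> int:
    """First zero-crossing lag of the autocorrelation, capped."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, min(cap, x.size - 1) + 1):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0:
            return lag
    return cap


def recurrence_matrix(x: np.ndarray, dim: int = RQA_DIM, delay: int | None = None,
                      eps_frac: float = RQA_EPS_FRAC) -> np.ndarray:
    """Boolean recurrence matrix of the time-delay embedded series."""
    x = np.asarray(x, dtype=float)
    if delay is None:
        delay = _autocorr_zero_delay(x)
    emb = _embed(x, dim, delay)
    dists = pdist(emb)
    eps = eps_frac * float(dists.max()) if dists.size else 0.0
    return squareform(dists <= eps) | np.eye(emb.shape[0], dtype=bool)


def recurrence_measures(x: np.ndarray, dim: int = RQA_DIM,
                        delay: int | None = None,
                        eps_frac: float = RQA_EPS_FRAC,
                        min_line: int = RQA_MIN_LINE,
                        max_samples: int = RQA_MAX_SAMPLES) -> tuple[float, float]:
    """Recurrence rate and determinism of the tremor series.

    The series is decimated to at most ``max_samples`` points (the matrix is
    O(n^2)).  RR is the recurrent fraction excluding the main diagonal; DET
    is the fraction of those recurrent points lying on diagonal lines of
    length >= ``min_line``.  A constant series is perfectly recurrent
    (RR = DET = 1).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 200:
        raise ValueError("need at least 200 samples for recurrence analysis")
    if x.size > max_samples:
        step = int(np.ceil(x.size / max_samples))
        x = x[::step]
    if np.ptp(x) == 0:
        return 1.0, 1.0
    rm = recurrence_matrix(x, dim, delay, eps_frac)
    n = rm.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_rec = int(np.count_nonzero(rm & off))
    rr = n_rec / (n * (n - 1))
    if n_rec == 0:
        return rr, 0.0
    in_lines = 0
    for k in range(1, n):
        diag = np.diagonal(rm, offset=k)
        # run lengths of consecutive recurrent points along this diagonal
        padded = np.concatenate([[0], diag.astype(int), [0]])
        edges = np.diff(padded)
        starts = np.where(edges == 1)[0]
        ends = np.where(edges == -1)[0]
        lengths = ends - starts
        in_lines += int(lengths[lengths >= min_line].sum())
    det = 2 * in_lines / n_rec  # both triangles
    return rr, float(det)


def tremor_stability_index(tremor: np.ndarray, fs: float,
                           band: tuple[float, float] | None = TSI_BAND_HZ) -> float:
    """IQR of consecutive differences of cycle-by-cycle tremor frequency.

    The tremor is band-passed to 2-12 Hz (``band=None`` skips the filter);
    cycles are delimited by positive-going zero crossings located to
    sub-sample precision by linear interpolation, each cycle's instantaneous
    frequency is the reciprocal of its duration, and the index is the
    interquartile range of the consecutive frequency changes.  A perfectly
    periodic tremor scores 0.
    """
    x = np.asarray(tremor, dtype=float)
    if band is not None:
        x = bandpass(x, fs, *band)
    pos = (x[:-1] < 0) & (x[1:] >= 0)
    idx = np.where(pos)[0]
    if idx.size < TSI_MIN_CYCLES + 1:
        return float("nan")
    # sub-sample crossing times by linear interpolation
    frac = -x[idx] / (x[idx + 1] - x[idx])
    times = (idx + frac) / fs
    freqs = 1.0 / np.diff(times)
    dfreq = np.diff(freqs)
    if dfreq.size < 2:
        return float("nan")
    q75, q25 = np.percentile(dfreq, [75, 25])
    return float(q75 - q25)


def gyro_change_rate(gyro_mag_bp: np.ndarray, fs: float, win_s: float = 1.0) -> float:
    """Max over 1-s windows of the mean absolute angular-velocity derivative."""
    x = np.asarray(gyro_mag_bp, dtype=float)
    win = int(round(win_s * fs))
    if x.size < win:
        raise ValueError("need at least one full window")
    deriv = np.abs(np.gradient(x, 1.0 / fs))
    n_win = x.size // win
    means = deriv[: n_win * win].reshape(n_win, win).mean(axis=1)
    return float(np.max(means))
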