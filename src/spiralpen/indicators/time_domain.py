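"""Time-domain indicators: kinematics, force, smoothness and tilt domains.

All computations here are 1-D and operate on the on-paper portion of the
conditioned signals (pen-in-air samples removed, segments concatenated):
force is undefined mid-air, and the drawing gesture is only observed while
the tip touches the paper.

Extremum detection is shared by several indicators and carries a prominence
guard: consecutive extrema whose amplitude swing is below 2% of the series'
interquartile range are pruned, so sensor noise does not inflate the
oscillation counts.  The guard is relative, which keeps every
coefficient-of-variation indicator invariant to positive rescaling of the
input.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import StrokeSegmentation

#: prominence guard as a fraction of the series' interquartile range
EXTREMA_GUARD_FRAC = 0.02

SPARC_THRESHOLDS = (10, 20, 30, 40, 45, 50)
SPARC_FMAX_HZ = 20.0
SPARC_GRID_HZ = 0.05


def find_extrema(x: np.ndarray, guard_frac: float = EXTREMA_GUARD_FRAC) -> np.ndarray:
    """Indices of local extrema of ``x`` after prominence pruning.

    Extrema are strict sign changes of the first difference (a plateau
    counts once, at its first sample).  Pairs of consecutive extrema whose
    amplitude difference is below ``guard_frac`` of the interquartile range
    are removed, smallest swing first, until none remain.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    sign = np.sign(d)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    idx = list(np.where(np.diff(sign) != 0)[0] + 1)
    q75, q25 = np.percentile(x, [75, 25])
    guard = guard_frac * (q75 - q25)
    if guard > 0:
        while len(idx) >= 2:
            vals = x[idx]
            swings = np.abs(np.diff(vals))
            k = int(np.argmin(swings))
            if swings[k] >= guard:
                break
            del idx[k:k + 2]
    return np.asarray(idx, dtype=int)


def execution_time(seg: StrokeSegmentation, fs: float) -> float:
    """Seconds from the first to the last on-paper sample (lifts included)."""
    if seg.n_strokes == 0:
        return float("nan")
    first = seg.stroke_intervals[0][0]
    last = seg.stroke_intervals[-1][1] - 1
    return (last - first + 1) / fs


def cons_peak_diff(x: np.ndarray) -> tuple[float, float]:
    """Average and CV of absolute differences between consecutive extrema."""
    idx = find_extrema(x)
    if idx.size < 3:
        return float("nan"), float("nan")
    d = np.abs(np.diff(np.asarray(x, dtype=float)[idx]))
    avg = float(np.mean(d))
    cv = float(np.std(d) / avg) if avg != 0 else float("nan")
    return avg, cv


def force_stats(force_on: np.ndarray) -> tuple[float, float, float]:
    """Mean, CV and overshoot (max - median) of the on-paper force."""
    force_on = np.asarray(force_on, dtype=float)
    if force_on.size < 10:
        raise ValueError("need at least 10 on-paper force samples")
    mean = float(np.mean(force_on))
    cv = float(np.std(force_on) / mean) if mean != 0 else float("nan")
    ovs = float(np.max(force_on) - np.median(force_on))
    return mean, cv, ovs


def rate_of_changes(x: np.ndarray, fs: float) -> float:
    """Local-extrema count per second of signal (NC_F / NC_A / NC_G)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan")
    return find_extrema(x).size / (x.size / fs)


def sparc(x: np.ndarray, fs: float, threshold_pct: float = 10.0) -> float:
    """Spectral arc length, a movement-smoothness metric (<= 0).

    The magnitude spectrum of the signal (zero-padded FFT, grid step below
    0.05 Hz) is normalized to its peak; the analysis cutoff is the highest
    frequency below 20 Hz where the normalized magnitude still exceeds
    ``threshold_pct`` of the peak; the metric is minus the arc length of the
    normalized spectrum over [0, cutoff] with frequency scaled by the cutoff.
    More negative means less smooth.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(max(x.size, fs / SPARC_GRID_HZ))))
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(x, n=nfft))
    sel = f <= SPARC_FMAX_HZ
    f, mag = f[sel], mag[sel]
    mhat = mag / np.max(mag)
    above = np.where(mhat >= threshold_pct / 100.0)[0]
    if above.size == 0 or above[-1] == 0:
        return float("nan")
    c = above[-1]
    wc = f[c]
    df = np.diff(f[: c + 1]) / wc
    dm = np.diff(mhat[: c + 1])
    return float(-np.sum(np.sqrt(df ** 2 + dm ** 2)))


def ldlj(x: np.ndarray, fs: float) -> float:
    """Log dimensionless squared jerk: ``-ln((T / peak^2) * int sdot^2 dt)``.

    ``T`` is the duration, ``peak`` the series' absolute maximum and the
    derivative is a central difference.  Dimensionless for any input order;
    more negative means less smooth.
    """
    x = np.asarray(x, dtype=float)
    peak = float(np.max(np.abs(x)))
    if x.size < 3 or peak == 0:
        return float("nan")
    T = x.size / fs
    ds = np.gradient(x, 1.0 / fs)
    integral = float(np.trapezoid(ds ** 2, dx=1.0 / fs))
    if integral <= 0:
        return float("nan")
    return float(-np.log(T / peak ** 2 * integral))


def tilt_stats(tilt_on: np.ndarray) -> tuple[float, float, float]:
    """Mean, population variance and CV of the on-paper tilt series."""
    tilt_on = np.asarray(tilt_on, dtype=float)
    if tilt_on.size < 10:
        raise ValueError("need at least 10 tilt samples")
    mean = float(np.mean(tilt_on))
    var = float(np.var(tilt_on))
    cv = float(np.sqrt(var) / mean) if abs(mean) > 1e-12 else float("nan")
    return mean, var, cv
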