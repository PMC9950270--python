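"""Signal conditioning: channel combination, band-pass filtering, pen tilt,
stroke / pen-lift segmentation and the quality-control rule.

The 1-D signals that feed the indicator computations are the Euclidean norms
of the tri-axial channels (rotation-invariant, the standard reduction for
hand-held IMU tremor work).  Kinematic norms are band-pass filtered to
2-12 Hz with a zero-phase 4th-order Butterworth filter; the "raw" norms are
mean-removed but unfiltered and feed the spectral indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import TooShortError, ValidationError
from .recording import PenRecording

BAND_HZ = (2.0, 12.0)
FILTER_ORDER = 4
TILT_CUTOFF_HZ = 1.0

#: pen-lift QC rule: a trace with more than this many internal lifts is excluded
MAX_PEN_LIFTS = 20

#: minimum stroke duration; shorter contact bursts are discarded
MIN_STROKE_S = 0.1


def bandpass(x: np.ndarray, fs: float, lo: float = BAND_HZ[0], hi: float = BAND_HZ[1],
             order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, reflective padding)."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise TooShortError("too short to filter")
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass used for gravity estimation."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise TooShortError("too short to filter")
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


@dataclass
class PreprocessedSignals:
    """Conditioned 1-D signals derived from one recording.

    ``*_bp`` are the 2-12 Hz band-passed norms, ``*_raw`` the mean-removed
    unfiltered norms, ``force`` the untouched force channel and ``tilt`` the
    pen inclination versus gravity in degrees.
    """

    fs: float
    acc_mag_bp: np.ndarray
    gyro_mag_bp: np.ndarray
    acc_mag_raw: np.ndarray
    gyro_mag_raw: np.ndarray
    force: np.ndarray
    tilt: np.ndarray


def compute_tilt(rec: PenRecording, axis: int = 2) -> np.ndarray:
    """Pen inclination angle versus gravity, in degrees, range [0, 180].

    The gravity vector is estimated by low-pass filtering the acceleration
    (2nd order Butterworth, 1 Hz cutoff, zero phase); tilt is the angle
    between the estimated gravity and the pen's long axis (device ``axis``,
    default z).
    """
    g = np.column_stack([lowpass(rec.acc[:, k], rec.fs, TILT_CUTOFF_HZ) for k in range(3)])
    norm = np.linalg.norm(g, axis=1)
    if np.any(norm < 0.1):
        raise ValidationError("free-fall / invalid gravity estimate")
    cosang = np.clip(g[:, axis] / norm, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def preprocess(rec: PenRecording, tilt_axis: int = 2) -> PreprocessedSignals:
    """Compute the conditioned signal set for one recording."""
    if rec.n_samples < rec.fs:
        raise TooShortError("recording shorter than 1 s")
    acc_mag = np.linalg.norm(rec.acc, axis=1)
    gyro_mag = np.linalg.norm(rec.gyro, axis=1)
    return PreprocessedSignals(
        fs=rec.fs,
        acc_mag_bp=bandpass(acc_mag, rec.fs),
        gyro_mag_bp=bandpass(gyro_mag, rec.fs),
        acc_mag_raw=acc_mag - acc_mag.mean(),
        gyro_mag_raw=gyro_mag - gyro_mag.mean(),
        force=rec.force.copy(),
        tilt=compute_tilt(rec, axis=tilt_axis),
    )


@dataclass
class StrokeSegmentation:
    """Tip-contact segmentation of one trial.

    ``stroke_intervals`` are half-open ``[start, end)`` sample-index
    intervals, disjoint and sorted; ``n_lifts`` counts only the off-paper
    gaps strictly between the first and last stroke (leading and trailing
    air time is not a lift).
    """

    n_strokes: int
    n_lifts: int
    stroke_intervals: list[tuple[int, int]]
    on_paper_mask: np.ndarray

    @property
    def any_contact(self) -> bool:
        return self.n_strokes > 0


def contact_threshold(force: np.ndarray, frac: float = 0.05, floor: float = 1e-3) -> float:
    """Adaptive contact threshold: ``max(frac x 95th percentile, noise floor)``.

    Device force units are uncalibrated, so the threshold adapts to the
    trial's own force level.
    """
    return max(frac * float(np.percentile(force, 95)), floor)


def segment_strokes(rec: PenRecording, threshold: float | None = None) -> StrokeSegmentation:
    """Detect strokes (tip-contact segments) from the force channel.

    Contact is entered when force exceeds the threshold and left when it
    drops below half of it (hysteresis); candidate strokes shorter than
    100 ms are discarded.
    """
    force = rec.force
    theta = contact_threshold(force) if threshold is None else float(threshold)
    enter, leave = theta, 0.5 * theta

    intervals: list[tuple[int, int]] = []
    on = False
    start = 0
    for i, f in enumerate(force):
        if not on and f > enter:
            on = True
            start = i
        elif on and f < leave:
            intervals.append((start, i))
            on = False
    if on:
        intervals.append((start, force.size))

    min_len = max(int(round(MIN_STROKE_S * rec.fs)), 1)
    intervals = [(a, b) for a, b in intervals if b - a >= min_len]

    mask = np.zeros(force.size, dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    n_strokes = len(intervals)
    n_lifts = max(n_strokes - 1, 0)
    return StrokeSegmentation(n_strokes, n_lifts, intervals, mask)


def qc_exclude(seg: StrokeSegmentation) -> bool:
    """Exclusion rule: ``True`` iff the trial has more than 20 pen lifts."""
    return seg.n_lifts > MAX_PEN_LIFTS
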