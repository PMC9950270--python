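"""Pen-recording data model and CSV I/O.

A trial is a uniformly sampled (50 Hz) multichannel record from a sensorized
ink pen: tri-axial acceleration (gravity included, m/s^2), tri-axial angular
velocity (deg/s) and the force exerted by the tip on the paper (uncalibrated
device units, >= 0).

The on-disk dialect is a plain CSV with header
``t,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z,force`` and an optional comment
line ``# units: s,m/s2,m/s2,m/s2,deg/s,deg/s,deg/s,au``.  Files that declare
acceleration in ``g`` are converted to m/s^2 (x 9.81) at read time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

G_TO_MS2 = 9.81

COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "force"]

#: maximum tolerated gap in the time grid, in sample periods: up to two
#: consecutive missing samples are restored by linear interpolation, a
#: larger gap is a hard error (tremor spectra are aliasing-sensitive)
MAX_GAP_PERIODS = 3.0

_T_TOL = 1e-9


@dataclass
class PenRecording:
    """One trial's validated signal set plus subject descriptors.

    Attributes
    ----------
    subject_id : str
    group : str
        ``"PD"`` or ``"control"``.
    hand : str
        ``"dominant"`` or ``"nondominant"``.
    trial : int
        Trial number (1 or 2).
    fs : float
        Sampling rate in Hz (nominally 50).
    t : ndarray
        Time stamps in seconds, uniform grid with step ``1/fs``.
    acc : ndarray, shape (n, 3)
        Acceleration in m/s^2, gravity included.
    gyro : ndarray, shape (n, 3)
        Angular velocity in deg/s.
    force : ndarray, shape (n,)
        Tip force in arbitrary device units, >= 0.
    """

    subject_id: str
    group: str
    hand: str
    trial: int
    fs: float
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError("acc/gyro must have shape (n, 3) matching t")
        if self.force.shape != (n,):
            raise ValidationError("force must have shape (n,) matching t")
        if self.group not in ("PD", "control"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.hand not in ("dominant", "nondominant"):
            raise ValidationError(f"unknown hand {self.hand!r}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValidationError(f"time not strictly increasing at row {i + 1}")
        if np.any(np.abs(dt - 1.0 / self.fs) > _T_TOL):
            i = int(np.argmax(np.abs(dt - 1.0 / self.fs) > _T_TOL))
            raise ValidationError(
                f"non-uniform time grid at row {i + 1}: dt={dt[i]:.6g}s, expected {1.0 / self.fs:.6g}s"
            )
        if np.any(self.force < 0):
            i = int(np.argmax(self.force < 0))
            raise ValidationError(f"negative force at row {i}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (inclusive of the last sample)."""
        return self.n_samples / self.fs


def _parse_units_comment(path_or_buf) -> list[str] | None:
    """Return the declared per-column units if a '# units:' comment exists."""
    if hasattr(path_or_buf, "read"):
        return None
    with open(path_or_buf, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("units:"):
                    return [u.strip() for u in body[len("units:"):].split(",")]
                continue
            break
    return None


def read_recording(
    path,
    metadata: Mapping | None = None,
    fs: float = 50.0,
) -> PenRecording:
    """Read one trial CSV and return a validated :class:`PenRecording`.

    Non-uniform timestamps are resampled onto the nominal ``1/fs`` grid by
    linear interpolation provided no gap reaches ``3/fs`` seconds; a larger
    gap raises :class:`ValidationError` naming the first offending row.
    """
    metadata = dict(metadata or {})
    units = _parse_units_comment(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[COLUMNS]
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: non-numeric or empty cell at row {row}")

    t = df["t"].to_numpy(dtype=float)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
    force = df["force"].to_numpy(dtype=float)

    if units is not None and len(units) >= 4:
        if units[1].lower() == "g":
            acc = acc * G_TO_MS2

    if np.any(force < 0):
        i = int(np.argmax(force < 0))
        raise ValidationError(f"{path}: negative force at row {i}")

    dt = np.diff(t)
    if t.size < 2:
        raise ValidationError(f"{path}: recording needs at least 2 samples")
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValidationError(f"{path}: time not increasing at row {i + 1}")
    period = 1.0 / fs
    if np.any(dt >= MAX_GAP_PERIODS * period - _T_TOL):
        bad = dt >= MAX_GAP_PERIODS * period - _T_TOL
        i = int(np.argmax(bad))
        raise ValidationError(
            f"{path}: gap of {dt[i]:.4g}s at row {i + 1} exceeds {MAX_GAP_PERIODS}/fs"
        )
    if np.any(np.abs(dt - period) > _T_TOL):
        # resample onto the nominal grid
        n_new = int(round((t[-1] - t[0]) * fs)) + 1
        t_new = t[0] + np.arange(n_new) / fs
        acc = np.column_stack([np.interp(t_new, t, acc[:, k]) for k in range(3)])
        gyro = np.column_stack([np.interp(t_new, t, gyro[:, k]) for k in range(3)])
        force = np.interp(t_new, t, force)
        t = t_new

    return PenRecording(
        subject_id=str(metadata.get("subject_id", "unknown")),
        group=str(metadata.get("group", "control")),
        hand=str(metadata.get("hand", "dominant")),
        trial=int(metadata.get("trial", 1)),
        fs=fs,
        t=t,
        acc=acc,
        gyro=gyro,
        force=force,
        meta=metadata,
    )


def write_recording(rec: PenRecording, path) -> None:
    """Write a trial to the recording CSV dialect (units comment included)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write("# units: s,m/s2,m/s2,m/s2,deg/s,deg/s,deg/s,au\n")
    buf.write(",".join(COLUMNS) + "\n")
    data = np.column_stack([rec.t, rec.acc, rec.gyro, rec.force])
    np.savetxt(buf, data, fmt="%.9g", delimiter=",")
    path.write_text(buf.getvalue(), encoding="utf-8")


METADATA_COLUMNS = [
    "subject_id", "group", "hand", "trial", "age", "sex", "mmse",
    "updrs3", "hy", "jankovic", "schiess", "kang",
    "updrs2_tremor", "updrs3_rest_tremor", "updrs3_hands",
]


def read_metadata(path) -> pd.DataFrame:
    """Read the subject metadata table (clinical columns may be empty)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("subject_id", "group", "hand") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {missing}")
    return df
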