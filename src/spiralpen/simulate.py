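"""Synthetic smart-pen recordings with the statistical structure the
analysis assumes.

No public recording of the clinical cohorts exists, so this module builds
pen trials whose signal ingredients mirror what the pipeline measures:

* a slow drawing oscillation (the loop-to-loop rhythm of tracing a spiral,
  ~0.8 Hz),
* an additive tremor with a per-subject center frequency in the
  parkinsonian 4-7 Hz band, controllable amplitude and cycle-to-cycle
  frequency jitter (the jitter is a direct ground-truth knob for the
  tremor stability index),
* a high-frequency ripple (8-12 Hz) degrading movement smoothness,
* a force profile with controllable mean, slow variability and oscillation
  rate, plus pen lifts inserted as zero-force gaps,
* broadband sensor noise and a gravity component at a realistic pen tilt.

Because the 1-D analysis signals are vector norms, a zero-mean dynamic
component only survives the norm through its projection on the dominant
axis (gravity for the accelerometer, the sustained loop rotation for the
gyro); all oscillatory ingredients are therefore injected with a fixed
0.7 projection onto that axis, and ground truth records the effective
(projected) tremor series.

The group presets encode the contrasts the pipeline is expected to detect
(patients: stronger and more stable tremor, more force oscillation, less
smooth kinematics, fewer pen lifts) without being fitted to any particular
device's units.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import PenRecording, write_recording

G_MS2 = 9.81
#: projection of each oscillatory ingredient onto the norm-dominant axis
AXIS_PROJECTION = 0.7


@dataclass
class SyntheticConfig:
    """Generation parameters for one group preset.

    Ranges are per-subject uniform draws; scalar fields are shared.
    Amplitudes are in m/s^2 (acceleration), deg/s (gyro) and arbitrary
    device units (force).
    """

    n_subjects: int = 29
    trials: int = 2
    duration_s: float = 30.0
    fs: float = 50.0
    group: str = "control"

    drawing_freq_hz: float = 0.8
    drawing_amp_acc: float = 0.6
    gyro_base_dps: float = 30.0
    gyro_loop_mod: float = 0.3          # fractional modulation of the loop speed

    #: drawing-related kinematic content inside the 2-12 Hz band: speed
    #: fluctuations while tracking the template, broadband around ~2-3.5 Hz
    harmonic_amp_acc: float = 0.15
    harmonic_freq_range: tuple[float, float] = (2.2, 3.5)
    harmonic_jitter_sd_hz: float = 0.3

    #: jerky, broadband angular-velocity content (7-13 Hz band-passed noise,
    #: deg/s RMS) degrading the smoothness of the drawing gesture
    gyro_jerk_amp_range: tuple[float, float] = (0.0, 0.5)

    tremor_freq_range: tuple[float, float] = (4.0, 7.0)
    tremor_amp_range: tuple[float, float] = (0.0, 0.05)
    tremor_gyro_per_acc: float = 30.0   # deg/s of gyro tremor per m/s^2 of acc tremor
    freq_jitter_sd_hz: float = 0.2

    ripple_amp_range: tuple[float, float] = (0.0, 0.05)
    ripple_freq_range: tuple[float, float] = (8.0, 12.0)

    force_mean: float = 300.0
    force_slow_amp: float = 0.15        # fractional slow modulation (CV knob)
    force_slow_freq_hz: float = 0.13
    force_osc_rate: float = 3.0         # extrema per second of the force oscillation
    force_osc_amp: float = 20.0
    force_noise_sd: float = 0.1

    n_lifts_mean: float = 2.5
    n_lifts: int | None = None          # fixed lift count, overrides the Poisson draw
    lift_dur_range: tuple[float, float] = (0.3, 0.6)
    lead_trail_s: float = 0.4           # off-paper time at both ends

    tilt_mean_deg: float = 40.0
    tilt_sd_deg: float = 5.0
    tilt_wander_deg: float = 2.0

    noise_sd_acc: float = 0.03
    noise_sd_gyro: float = 0.3

    def validate(self) -> None:
        for name in ("drawing_amp_acc", "gyro_base_dps", "force_mean",
                     "force_osc_amp", "noise_sd_acc", "noise_sd_gyro"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tremor_amp_range", "ripple_amp_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative range")
        if self.duration_s * self.fs < 500:
            raise ValueError("duration must cover at least one 500-sample window")


#: patients: strong, frequency-stable tremor; degraded smoothness; faster
#: force oscillation; few pen lifts
PD_PRESET = SyntheticConfig(
    group="PD",
    tremor_amp_range=(0.3, 0.8),
    freq_jitter_sd_hz=0.1,
    harmonic_amp_acc=0.05,
    tremor_gyro_per_acc=20.0,
    ripple_amp_range=(0.03, 0.08),
    gyro_jerk_amp_range=(15.0, 25.0),
    force_slow_amp=0.25,
    force_osc_rate=4.0,
    n_lifts_mean=0.7,
)

#: controls: negligible tremor, smooth kinematics, more pen lifts
CONTROL_PRESET = SyntheticConfig(
    group="control",
    tremor_amp_range=(0.0, 0.05),
    freq_jitter_sd_hz=0.8,
    harmonic_jitter_sd_hz=0.5,
    ripple_amp_range=(0.0, 0.02),
    gyro_jerk_amp_range=(0.0, 0.5),
    force_slow_amp=0.15,
    force_osc_rate=3.0,
    n_lifts_mean=2.5,
)


@dataclass
class GroundTruth:
    """Injected parameters and effective tremor series for one trial."""

    tremor_series: np.ndarray       # effective (projected) tremor in the acc norm
    tremor_freq_hz: float
    tremor_amp: float
    cycle_freqs: np.ndarray
    params: dict = field(default_factory=dict)


@dataclass
class _SubjectParams:
    subject_id: str
    harmonic_freq: float
    tremor_freq: float
    tremor_amp: float
    ripple_amp: float
    ripple_freq: float
    gyro_jerk_amp: float
    tilt0: float
    severity: float          # normalized tremor amplitude, drives clinical scores


def _draw_subject(cfg: SyntheticConfig, idx: int, rng: np.random.Generator) -> _SubjectParams:
    lo, hi = cfg.tremor_amp_range
    amp = rng.uniform(lo, hi)
    sev = (amp - lo) / (hi - lo) if hi > lo else 0.0
    return _SubjectParams(
        subject_id=f"{cfg.group}{idx + 1:03d}",
        harmonic_freq=rng.uniform(*cfg.harmonic_freq_range),
        tremor_freq=rng.uniform(*cfg.tremor_freq_range),
        tremor_amp=amp,
        ripple_amp=rng.uniform(*cfg.ripple_amp_range),
        ripple_freq=rng.uniform(*cfg.ripple_freq_range),
        gyro_jerk_amp=rng.uniform(*cfg.gyro_jerk_amp_range),
        tilt0=rng.normal(cfg.tilt_mean_deg, cfg.tilt_sd_deg),
        severity=sev,
    )


def jittered_tremor_wave(n: int, fs: float, f0: float, jitter_sd: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Phase-continuous sinusoid whose frequency is redrawn every cycle.

    Each cycle's frequency is Normal(f0, jitter_sd) (floored at 0.5 Hz) and
    the phase advances by exactly 2*pi per cycle, so the per-cycle
    frequency list is the exact ground truth for cycle-based indicators.
    """
    t_total = n / fs
    freqs = []
    t_acc = 0.0
    while t_acc <= t_total + 1.0:
        f = max(rng.normal(f0, jitter_sd), 0.5)
        freqs.append(f)
        t_acc += 1.0 / f
    freqs = np.asarray(freqs)
    bounds = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    t = np.arange(n) / fs
    idx = np.searchsorted(bounds, t, side="right") - 1
    phase = 2 * np.pi * (idx + (t - bounds[idx]) * freqs[idx])
    return np.sin(phase), freqs


def _projected_direction(dominant: np.ndarray, rng: np.random.Generator,
                         proj: float = AXIS_PROJECTION) -> np.ndarray:
    """Unit vector with a fixed projection onto ``dominant``."""
    dominant = dominant / np.linalg.norm(dominant)
    v = rng.normal(size=3)
    v -= v @ dominant * dominant
    v /= np.linalg.norm(v)
    return proj * dominant + np.sqrt(1 - proj ** 2) * v


def _lift_gaps(cfg: SyntheticConfig, n_lifts: int, rng: np.random.Generator,
               t: np.ndarray) -> list[tuple[float, float]]:
    """Non-overlapping zero-force gaps strictly inside the trace."""
    if n_lifts <= 0:
        return []
    duration = t[-1]
    slots = np.linspace(0.15, 0.85, n_lifts + 2)[1:-1] * duration
    gaps = []
    for c in slots:
        width = rng.uniform(*cfg.lift_dur_range)
        c = c + rng.uniform(-0.05, 0.05) * duration / (n_lifts + 1)
        gaps.append((c - width / 2, c + width / 2))
    return gaps


def generate_trial(cfg: SyntheticConfig, sp: _SubjectParams, trial: int,
                   rng: np.random.Generator, hand: str = "dominant",
                   ) -> tuple[PenRecording, GroundTruth]:
    """Build one trial for one subject; deterministic given the rng state."""
    cfg.validate()
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    # gravity at a slowly wandering pen tilt
    theta = np.radians(sp.tilt0 + cfg.tilt_wander_deg
                       * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi)))
    g_dir = np.column_stack([np.sin(theta), np.zeros(n), np.cos(theta)])
    g0 = np.array([np.sin(np.radians(sp.tilt0)), 0.0, np.cos(np.radians(sp.tilt0))])

    tremor_wave, cycle_freqs = jittered_tremor_wave(
        n, cfg.fs, sp.tremor_freq, cfg.freq_jitter_sd_hz, rng)
    drawing = cfg.drawing_amp_acc * np.sin(
        2 * np.pi * cfg.drawing_freq_hz * t + rng.uniform(0, 2 * np.pi))
    harmonic_wave, _ = jittered_tremor_wave(
        n, cfg.fs, sp.harmonic_freq, cfg.harmonic_jitter_sd_hz, rng)
    harmonic = cfg.harmonic_amp_acc * harmonic_wave
    ripple = sp.ripple_amp * np.sin(
        2 * np.pi * sp.ripple_freq * t + rng.uniform(0, 2 * np.pi))

    d_dir = _projected_direction(g0, rng)
    h_dir = _projected_direction(g0, rng)
    t_dir = _projected_direction(g0, rng)
    r_dir = _projected_direction(g0, rng)
    acc = (G_MS2 * g_dir
           + np.outer(drawing, d_dir)
           + np.outer(harmonic, h_dir)
           + np.outer(sp.tremor_amp * tremor_wave, t_dir)
           + np.outer(ripple, r_dir)
           + rng.normal(0, cfg.noise_sd_acc, size=(n, 3)))

    # gyro: sustained loop rotation plus the same oscillatory ingredients
    b_dir = np.array([0.3, 0.9, 0.3])
    b_dir /= np.linalg.norm(b_dir)
    loop = cfg.gyro_base_dps * (1 + cfg.gyro_loop_mod * np.sin(
        2 * np.pi * cfg.drawing_freq_hz * t + rng.uniform(0, 2 * np.pi)))
    jerk = np.zeros(n)
    if sp.gyro_jerk_amp > 0:
        from .preprocess import bandpass
        jerk = bandpass(rng.normal(size=n), cfg.fs, 7.0, 13.0)
        jerk *= sp.gyro_jerk_amp / jerk.std()
    tg_dir = _projected_direction(b_dir, rng)
    hg_dir = _projected_direction(b_dir, rng)
    rg_dir = _projected_direction(b_dir, rng)
    jg_dir = _projected_direction(b_dir, rng)
    gyro = (np.outer(loop, b_dir)
            + np.outer(jerk, jg_dir)
            + np.outer(sp.tremor_amp * cfg.tremor_gyro_per_acc * tremor_wave, tg_dir)
            + np.outer(harmonic * cfg.tremor_gyro_per_acc, hg_dir)
            + np.outer(ripple * cfg.tremor_gyro_per_acc, rg_dir)
            + rng.normal(0, cfg.noise_sd_gyro, size=(n, 3)))

    # force with slow modulation, an oscillation at the target extrema rate,
    # lead/trail air time and internal pen lifts
    slow = np.sin(2 * np.pi * cfg.force_slow_freq_hz * t + rng.uniform(0, 2 * np.pi))
    osc = cfg.force_osc_amp * np.sin(np.pi * cfg.force_osc_rate * t
                                     + rng.uniform(0, 2 * np.pi))
    force = cfg.force_mean * (1 + cfg.force_slow_amp * slow) + osc
    force += rng.normal(0, cfg.force_noise_sd, size=n)
    force[t < cfg.lead_trail_s] = 0.0
    force[t > t[-1] - cfg.lead_trail_s] = 0.0
    n_lifts = cfg.n_lifts if cfg.n_lifts is not None else int(rng.poisson(cfg.n_lifts_mean))
    for a, b in _lift_gaps(cfg, n_lifts, rng, t):
        force[(t >= a) & (t < b)] = 0.0
    np.clip(force, 0.0, None, out=force)

    rec = PenRecording(subject_id=sp.subject_id, group=cfg.group, hand=hand,
                       trial=trial, fs=cfg.fs, t=t, acc=acc, gyro=gyro, force=force)
    gt = GroundTruth(
        tremor_series=sp.tremor_amp * AXIS_PROJECTION * tremor_wave,
        tremor_freq_hz=sp.tremor_freq,
        tremor_amp=sp.tremor_amp,
        cycle_freqs=cycle_freqs,
        params={"subject_id": sp.subject_id, "trial": trial,
                "ripple_amp": sp.ripple_amp, "n_lifts": n_lifts,
                "severity": sp.severity},
    )
    return rec, gt


def _clinical_scores(sp: _SubjectParams, rng: np.random.Generator) -> dict:
    """Noisy monotone transforms of injected severity (rank structure only)."""
    sev = sp.severity

    def score(base, slope, noise, lo, hi, integer=True):
        v = base + slope * sev + rng.normal(0, noise)
        v = float(np.clip(v, lo, hi))
        return round(v) if integer else round(v, 2)

    return {
        "updrs3": score(10, 25, 12, 5, 60),
        "hy": score(1, 2.5, 1.2, 1, 5),
        "jankovic": score(0.5, 2.0, 1.0, 0, 3, integer=False),
        "schiess": score(0.5, 2.0, 1.0, 0, 3, integer=False),
        "kang": score(0.5, 2.0, 1.0, 0, 3, integer=False),
        "updrs2_tremor": score(0.5, 3.0, 1.5, 0, 4),
        "updrs3_rest_tremor": score(0.5, 3.0, 1.5, 0, 4),
        "updrs3_hands": score(2, 10, 5, 0, 20),
    }


def generate_cohorts(pd_cfg: SyntheticConfig = PD_PRESET,
                     control_cfg: SyntheticConfig = CONTROL_PRESET,
                     seed: int = 0,
                     ) -> tuple[list[PenRecording], list[GroundTruth], pd.DataFrame]:
    """Generate a patient-like and a control-like cohort (dominant hand).

    Returns all trial recordings, their ground truths, and a one-row-per-
    subject metadata table with synthetic clinical scores whose ranks
    correlate moderately with the injected tremor amplitude (so the
    correlation stage has signal to find).
    """
    rng = np.random.default_rng(seed)
    recordings: list[PenRecording] = []
    truths: list[GroundTruth] = []
    meta_rows = []
    for cfg in (pd_cfg, control_cfg):
        cfg.validate()
        for i in range(cfg.n_subjects):
            sp = _draw_subject(cfg, i, rng)
            row = {"subject_id": sp.subject_id, "group": cfg.group,
                   "hand": "dominant",
                   "trial": "",
                   "age": round(float(np.clip(rng.normal(72, 8), 40, 95))),
                   "sex": rng.choice(["M", "F"]),
                   "mmse": round(float(np.clip(rng.normal(28, 1.5), 24, 30)))}
            if cfg.group == "PD":
                row.update(_clinical_scores(sp, rng))
            else:
                row.update({k: "" for k in ("updrs3", "hy", "jankovic", "schiess",
                                            "kang", "updrs2_tremor",
                                            "updrs3_rest_tremor", "updrs3_hands")})
            meta_rows.append(row)
            for trial in range(1, cfg.trials + 1):
                rec, gt = generate_trial(cfg, sp, trial, rng)
                recordings.append(rec)
                truths.append(gt)
    meta = pd.DataFrame(meta_rows)
    return recordings, truths, meta


def write_cohort(out_dir, recordings: list[PenRecording], meta: pd.DataFrame) -> None:
    """Write trial CSVs (one per trial) and the metadata table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out_dir / f"{rec.subject_id}_{rec.hand}_t{rec.trial}.csv")
    meta.to_csv(out_dir / "meta.csv", index=False)


def preset(name: str, **overrides) -> SyntheticConfig:
    """Named preset (``"pd"`` or ``"control"``) with optional overrides."""
    base = {"pd": PD_PRESET, "control": CONTROL_PRESET}[name.lower()]
    return replace(base, **overrides)
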