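import numpy as np
import pytest

from spiralpen import PenRecording


def make_recording(acc=None, gyro=None, force=None, n=500, fs=50.0, **meta):
    """Minimal valid recording; unspecified channels default to rest-like."""
    t = np.arange(n) / fs
    if acc is None:
        acc = np.tile([0.0, 0.0, 9.81], (n, 1))
    if gyro is None:
        gyro = np.zeros((n, 3))
    if force is None:
        force = np.full(n, 10.0)
    return PenRecording(
        subject_id=meta.get("subject_id", "s1"),
        group=meta.get("group", "control"),
        hand=meta.get("hand", "dominant"),
        trial=meta.get("trial", 1),
        fs=fs, t=t, acc=np.asarray(acc, float),
        gyro=np.asarray(gyro, float), force=np.asarray(force, float),
    )


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small patient/control cohort shared by pipeline-level tests."""
    from dataclasses import replace

    from spiralpen import CONTROL_PRESET, PD_PRESET, generate_cohorts

    return generate_cohorts(replace(PD_PRESET, n_subjects=5),
                            replace(CONTROL_PRESET, n_subjects=5), seed=11)
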