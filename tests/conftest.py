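import numpy as np
import pytest

from fidgetlab import generate_cohort, segment_cohort
from fidgetlab.config import CohortConfig
from fidgetlab.synthetic import (AnnotationInterval, Recording, N_SENSORS,
                                 N_POSE_CHANNELS)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six confounded subjects of 40 s each, plus the manifest."""
    cfg = CohortConfig(duration_fixed_s=40.0)
    recordings, manifest = generate_cohort(6, cfg, rng_seed=123)
    return recordings, manifest


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    recordings, _ = tiny_cohort
    return segment_cohort(recordings)


def make_recording(duration_s=10.0, annotations=(), subject_id="T000",
                   freq_hz=1.3, noise=0.01, seed=0, imu_hz=200.0,
                   pose_hz=30.0):
    """Hand-built recording: per-channel sinusoids plus a little noise.

    Gives tests full control over the annotation layout without going
    through the synthetic generator.
    """
    rng = np.random.default_rng(seed)
    n_imu = int(np.floor(duration_s * imu_hz)) + 1
    t_imu = np.arange(n_imu) / imu_hz
    imu_t, imu = [], []
    for s in range(N_SENSORS):
        # acceleration channels share the pose phase (so movement-intensity
        # traces correlate across modalities); gyro phases are free
        phases = np.concatenate([np.zeros(3), rng.uniform(0, 2 * np.pi, 3)])
        sig = np.stack([np.sin(2 * np.pi * freq_hz * t_imu + ph)
                        for ph in phases], axis=1)
        sig += rng.normal(0, noise, sig.shape)
        imu_t.append(t_imu.copy())
        imu.append(sig)
    n_pose = int(np.floor(duration_s * pose_hz)) + 1
    t_pose = np.arange(n_pose) / pose_hz
    pose = np.sin(2 * np.pi * freq_hz * t_pose)[:, None] * \
        rng.uniform(0.5, 1.0, N_POSE_CHANNELS)[None, :]
    pose += rng.normal(0, noise, pose.shape)
    return Recording(subject_id=subject_id, imu_t=imu_t, imu=imu,
                     pose_t=t_pose, pose=pose,
                     annotations=[AnnotationInterval(*a) for a in annotations],
                     duration_s=duration_s).validate()
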