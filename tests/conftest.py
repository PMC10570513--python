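import numpy as np
import pytest

from imugait.pipeline import StudyConfig, build_study_dataset
from imugait.simulate import GaitSimConfig, HingeSimConfig, simulate_gait, simulate_hinge


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture(scope="session")
def zero_noise_hinge():
    """Noise-free 20 s hinge recording with oblique axes and offsets."""
    cfg = HingeSimConfig(
        duration=20.0,
        rate=60.0,
        true_axis_1=unit([0.2, 0.9, 0.3]),
        true_axis_2=unit([-0.1, 0.8, 0.5]),
        true_center_1=np.array([0.06, -0.03, -0.18]),
        true_center_2=np.array([0.02, 0.05, 0.14]),
        seed=1,
    )
    return cfg, simulate_hinge(cfg)


@pytest.fixture(scope="session")
def noisy_hinge():
    """60 s hinge recording at realistic IMU noise/bias levels."""
    rng = np.random.default_rng(21)
    cfg = HingeSimConfig(
        duration=60.0,
        rate=60.0,
        true_axis_1=unit(rng.normal(size=3)),
        true_axis_2=unit(rng.normal(size=3)),
        true_center_1=rng.uniform(-0.15, 0.15, 3),
        true_center_2=rng.uniform(-0.15, 0.15, 3),
        gyro_noise_sd=0.01,
        accel_noise_sd=0.1,
        gyro_bias=0.005,
        seed=2,
    )
    return cfg, simulate_hinge(cfg)


@pytest.fixture(scope="session")
def gait_trials():
    """Two-subject, four-speed synthetic gait study (noisy sensors)."""
    cfg = GaitSimConfig(n_subjects=2, strides_per_speed=6, seed=3)
    return cfg, simulate_gait(cfg)


@pytest.fixture(scope="session")
def clean_gait_trial():
    """Single noise-free trial for oracle-grade label checks."""
    cfg = GaitSimConfig(
        n_subjects=1,
        strides_per_speed=6,
        seed=4,
        gyro_noise_sd=0.0,
        accel_noise_sd=0.0,
        gyro_bias=0.0,
        grf_noise_rel=0.0,
    )
    return cfg, simulate_gait(cfg)[0]


@pytest.fixture(scope="session")
def study_dataset():
    """Six-subject end-to-end cycle dataset with estimated geometry."""
    cfg = StudyConfig(
        gait=GaitSimConfig(n_subjects=6, strides_per_speed=5, seed=7),
        inter_subjects=(4, 5),
        seed=7,
    )
    dataset, _ = build_study_dataset(cfg)
    return cfg, dataset
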