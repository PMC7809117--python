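import numpy as np
import pytest

from hyoidkin import SyntheticCohortConfig, generate_cohort
from hyoidkin.kinematics import (
    KinematicProfile,
    compute_direction_angles,
    compute_velocity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort shared by pipeline-level tests."""
    cfg = SyntheticCohortConfig(n_good=5, n_poor=5)
    series, truths, labels = generate_cohort(cfg, seed=7)
    return cfg, series, truths, labels


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, drift-free generator configuration."""
    return SyntheticCohortConfig(
        n_good=2,
        n_poor=2,
        pixel_noise_sd=0.0,
        drift_rot_sd=0.0,
        drift_trans_sd=0.0,
    )


def make_profile(disp_x, disp_y, duration_s=1.5, with_velocity=True, with_angle=True):
    """Profile on the standard 101-point grid from displacement arrays."""
    disp_x = np.asarray(disp_x, dtype=float)
    profile = KinematicProfile(
        grid=np.linspace(0.0, 100.0, len(disp_x)),
        disp_x=disp_x,
        disp_y=np.asarray(disp_y, dtype=float),
        duration_s=duration_s,
    )
    if with_velocity:
        compute_velocity(profile)
        if with_angle:
            compute_direction_angles(profile)
    return profile
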