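import numpy as np
import pytest

from gaitphase.kinematics import TrialRecording
from gaitphase.simulate import VariabilityModel, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x C2-C5 x 1 trial with default variability."""
    return generate_cohort(8, ["C2", "C3", "C4", "C5"], 1, seed=42)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort for exactness checks."""
    return generate_cohort(4, ["C2", "C3"], 1,
                           variability=VariabilityModel.zero(), seed=7)


def make_recording(n_labeled: int, fs: float = 100.0,
                   n_channels_value: float = 0.0) -> TrialRecording:
    """A trial with exactly ``n_labeled`` labeled samples.

    Heel-strikes at t=0 and half a sample past the (n_labeled-1)-th sample,
    so samples 0 .. n_labeled-1 are labeled and the rest are not.
    """
    n = n_labeled + 20
    t = np.arange(n) / fs
    hs = np.array([0.0, 0.25 * (n_labeled - 0.5) / fs,
                   (n_labeled - 0.5) / fs])
    z = np.full(n, n_channels_value)
    return TrialRecording(
        subject_id="SX", condition="C3", time_s=t,
        thigh_angle_deg=np.sin(t), thigh_vel_dps=np.cos(t),
        torso_angle_deg=z, torso_vel_dps=z,
        heel_strikes_s=hs, toe_offs_s=np.array([]), sampling_rate=fs)
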