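import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pafosim import (GaitParams, forward_markers, generate_grf,
                     generate_joint_angles, scale_model)

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

REF_HEIGHT, REF_MASS = 1.71, 68.03


@pytest.fixture(scope="session")
def model():
    return scale_model(REF_HEIGHT, REF_MASS, "ref")


@pytest.fixture(scope="session")
def gait(model):
    """Default-template gait cycle with GRFs and noiseless markers."""
    cycle = generate_joint_angles(GaitParams(), model)
    cycle = generate_grf(cycle, model.body_mass, model=model)
    forward_markers(model, cycle, noise_sd=0.0)
    return cycle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
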