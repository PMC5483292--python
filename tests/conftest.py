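import numpy as np
import pytest

from thermoface import build_default_schedule
from thermoface.phantom import PhantomConfig, face_template


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def small_config():
    """Half-scale phantom (120 x 160): identical structure, faster warps."""
    return PhantomConfig().scaled(0.5)


@pytest.fixture(scope="session")
def small_template(small_config):
    return face_template(small_config)


@pytest.fixture(scope="session")
def clean_small_config():
    """Half-scale phantom with every stochastic term switched off."""
    return PhantomConfig(
        jitter_translation_sd=0.0,
        jitter_rotation_sd=0.0,
        jitter_scale_sd=0.0,
        noise_sd=0.0,
        physio_sd=0.0,
        drift_per_min=0.0,
        between_subject_sd=0.0,
    ).scaled(0.5)


def two_group_data(rng, n1=18, n2=17, k=9, gap=0.0):
    """Random two-group score matrix with an optional mean gap on axis 0."""
    X = rng.normal(size=(n1 + n2, k))
    X[n1:, 0] += gap
    y = np.array(["moderate"] * n1 + ["marked"] * n2)
    return X, y
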