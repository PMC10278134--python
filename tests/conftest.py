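import numpy as np
import pytest

from blufspec import FixtureConfig, compute_modes, gen_toy_hessian


@pytest.fixture
def diatomic():
    """Homonuclear diatomic: one vibration at sqrt(k/mu), mu = 0.5 amu."""
    spec = {
        "masses": [1.0, 1.0],
        "positions": [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
        "bonds": [[0, 1, 1.0]],
    }
    return gen_toy_hessian(spec)


@pytest.fixture
def co2_like():
    """Symmetric linear triatomic with equal springs (closed-form stretches)."""
    spec = {
        "masses": [15.999, 12.011, 15.999],
        "positions": [[-1.16, 0.0, 0.0], [0.0, 0.0, 0.0], [1.16, 0.0, 0.0]],
        "bonds": [[0, 1, 0.8], [1, 2, 0.8]],
    }
    return gen_toy_hessian(spec)


@pytest.fixture
def water_like():
    """Bent triatomic with two bonds plus an H-H spring (3 real modes)."""
    spec = {
        "masses": [15.999, 1.008, 1.008],
        "positions": [[0.0, 0.0, 0.0], [0.76, 0.59, 0.0], [-0.76, 0.59, 0.0]],
        "bonds": [[0, 1, 0.5], [0, 2, 0.5], [1, 2, 0.1]],
    }
    return gen_toy_hessian(spec)


@pytest.fixture
def diatomic_modes(diatomic):
    h, m, c = diatomic
    return compute_modes(h, m, c)


@pytest.fixture
def small_cfg():
    return FixtureConfig(seed=11, n_frames=100)


def random_rigid_motion(rng):
    """Random rotation matrix + translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-10.0, 10.0, 3)
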