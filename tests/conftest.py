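import numpy as np
import pytest

import signcomp as sc


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: subclass counts (6, 4, 3, 3, 6)."""
    return sc.make_world(seed=1)


@pytest.fixture(scope="session")
def truth_inventory(world):
    """Ground-truth inventory measured from a noiseless calibration batch."""
    return sc.world_inventory(world)


@pytest.fixture(scope="session")
def small_dataset(world):
    """24 gestures x 3 repetitions at the world's default (moderate) noise."""
    return sc.generate_dataset(24, 3, world, seed=3)


@pytest.fixture(scope="session")
def clean_dataset(world):
    """Noiseless copy of the small vocabulary (2 repetitions)."""
    return sc.generate_dataset(12, 2, world, seed=3, noise=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_recording(rng, ns=2200, hands="right", **kwargs):
    """A structurally valid random recording (not from the generator)."""
    na = ns // 10
    def hand():
        return sc.HandSignals(
            semg=rng.normal(scale=0.2, size=(4, ns)),
            acc=rng.normal(scale=0.3, size=(3, na)) + np.array([[0], [0], [1.0]]),
            gyro=rng.normal(scale=20.0, size=(3, na)),
        )
    defaults = dict(subject_id="S1", gesture_id="G001", repetition=1)
    defaults.update(kwargs)
    return sc.GestureRecording(
        hands=hands, right=hand(), left=hand() if hands == "both" else None,
        **defaults)
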