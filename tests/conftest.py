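import numpy as np
import pytest

from myofitts.features import build_feature_table
from myofitts.simulate import (
    AcquisitionConfig,
    GestureProtocol,
    default_pattern,
    generate_session,
    offline_protocol,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def offline_session(acq):
    """A full nine-gesture, four-repetition session (the offline protocol)."""
    proto = offline_protocol()
    return generate_session(proto, default_pattern(proto), acq, "gel", seed=1)


@pytest.fixture(scope="session")
def offline_table(offline_session):
    return build_feature_table(offline_session)


@pytest.fixture(scope="session")
def small_session(acq):
    """A three-gesture, two-repetition session for cheap structural tests."""
    proto = GestureProtocol(
        gesture_labels=("open_hand", "wrist_flexion", "rest"), reps_per_gesture=2
    )
    return generate_session(proto, default_pattern(proto), acq, "gel", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
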