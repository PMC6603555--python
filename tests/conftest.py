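import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from falldet import AccelStream, REFERENCE_THRESHOLDS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_hand_trace_xyz() -> np.ndarray:
    """Four-phase piecewise-constant fall at 100 Hz: 1 s upright, 0.3 s of
    0.15 g free fall along +x, one 3 g impact sample along +x, 6 s lying on
    +x.  Hand-traceable through every transition rule."""
    return np.vstack([
        np.tile([0.0, 0.0, 1.0], (100, 1)),
        np.tile([0.15, 0.0, 0.0], (30, 1)),
        np.array([[3.0, 0.0, 0.0]]),
        np.tile([1.0, 0.0, 0.0], (600, 1)),
    ])


@pytest.fixture(scope="session")
def hand_trace_stream() -> AccelStream:
    return AccelStream.from_arrays(build_hand_trace_xyz(), 100)


@pytest.fixture(scope="session")
def ref_thresholds():
    return REFERENCE_THRESHOLDS


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
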