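import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadkin import DyadSimConfig, JointTrack, SkeletonStream, simulate_dyad

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20160524)


def make_stream(
    positions,
    timestamps=None,
    orientation=None,
    partner="mother",
    valid=None,
    frame_id="common",
):
    """Build a SkeletonStream from {joint: (T,3) array}."""
    positions = {k: np.asarray(v, dtype=float) for k, v in positions.items()}
    T = len(next(iter(positions.values())))
    if timestamps is None:
        timestamps = np.arange(T) / 30.0
    if orientation is None:
        orientation = np.tile([1.0, 0.0, 0.0], (T, 1))
    joints = {}
    for name, pos in positions.items():
        v = np.ones(T, dtype=bool) if valid is None else np.asarray(
            valid[name] if isinstance(valid, dict) else valid, dtype=bool
        )
        joints[name] = JointTrack(name, pos, v)
    return SkeletonStream(
        partner=partner,
        timestamps=np.asarray(timestamps, dtype=float),
        joints=joints,
        head_orientation=np.asarray(orientation, dtype=float),
        frame_id=frame_id,
    )


@pytest.fixture(scope="session")
def short_dyad():
    """A 40 s simulated dyad shared by read-only tests."""
    return simulate_dyad(DyadSimConfig(duration=40.0, seed=11))
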