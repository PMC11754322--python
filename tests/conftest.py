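import numpy as np
import pytest

import explometrics as em
from explometrics.trajio import MeasureParams, Trajectory


def make_traj(points, hz=10.0, subject_id="t", times=None):
    points = np.asarray(points, dtype=float)
    return Trajectory(
        subject_id=subject_id,
        points=points,
        times=times,
        sample_rate_hz=hz,
    )


@pytest.fixture(scope="session")
def fixture_lib():
    return em.fixtures()


@pytest.fixture(scope="session")
def env140():
    return em.make_environment(140, 140, 14, n_landmarks=20, layout="grid", seed=1)


@pytest.fixture(scope="session")
def params():
    return MeasureParams(rediscretize_step=0.48)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
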