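import numpy as np
import pytest

from dynenv.datatypes import ParticleTrajectory, SignalEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cloud(rng):
    """50 random points in an open 10^3 box, one frame."""
    pos = rng.random((50, 1, 3)) * 10.0
    return ParticleTrajectory(positions=pos, box=[10.0, 10.0, 10.0],
                              periodic=[False, False, False])


@pytest.fixture
def two_group_ensemble(rng):
    """Static, well-separated groups: 100 series at 0 and 100 at 5."""
    vals = np.concatenate([rng.normal(0.0, 0.1, (100, 500)),
                           rng.normal(5.0, 0.1, (100, 500))])
    return SignalEnsemble(values=vals)
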