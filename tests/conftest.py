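import numpy as np
import pytest

from dynlogic.observations import Domain, ObservationSet
from dynlogic.scenes import ArcSpec, SceneSpec


@pytest.fixture
def unit_domain():
    return Domain(1.0, 1.0)


@pytest.fixture
def square64():
    return Domain(64.0, 64.0)


@pytest.fixture
def simple_arc():
    return ArcSpec(
        vertex_x=32.0,
        vertex_y=40.0,
        curvature=0.05,
        rotation=np.pi,
        half_extent=14.0,
        transverse_sigma=1.0,
    )


@pytest.fixture
def noise_spec():
    return SceneSpec(domain_width=64, domain_height=64, noise_sigma=1.0, seed=7)


@pytest.fixture
def point_obs():
    rng = np.random.default_rng(11)
    xy = rng.uniform(0, 10, size=(40, 2))
    return ObservationSet(
        ids=np.arange(40),
        weights=np.ones(40),
        dialect="points",
        positions=xy,
        domain=Domain(10.0, 10.0),
    )


@pytest.fixture
def feature_obs():
    rng = np.random.default_rng(5)
    x = (rng.uniform(size=(30, 6)) < 0.4).astype(float)
    return ObservationSet(
        ids=np.arange(30),
        weights=np.ones(30),
        dialect="features",
        features=x,
    )
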