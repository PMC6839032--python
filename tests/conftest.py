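import numpy as np
import pytest

from rhizotrace.core import ArchitectureParams, Plant, Root, RootSystem
from rhizotrace.synthetic import fibrous_params, generate_architecture, taproot_params


@pytest.fixture
def straight_root_system():
    """One plant, one vertical order-1 root from (50, 10) to (50, 110)."""
    root = Root(order=1, points=np.array([[50.0, 10.0], [50.0, 110.0]]))
    return RootSystem(plants=[Plant(seed=np.array([50.0, 10.0]), roots=[root])])


@pytest.fixture
def forked_root_system():
    """A vertical primary with one 45-degree lateral attached mid-way."""
    primary = Root(order=1, points=np.array([[100.0, 20.0], [100.0, 220.0]]))
    lateral = Root(
        order=2,
        points=np.array([[100.0, 120.0], [140.0, 160.0]]),
        parent=primary,
        attachment=np.array([100.0, 120.0]),
    )
    plant = Plant(seed=np.array([100.0, 20.0]), roots=[primary, lateral])
    return RootSystem(plants=[plant])


@pytest.fixture
def small_fibrous_params():
    return fibrous_params(
        n_first_order=(3, 3),
        laterals_per_root=(1, 2),
        image_size=(384, 384),
        growth_length=(150.0, 260.0),
        lateral_length=(70.0, 110.0),
        rng_seed=11,
    )


@pytest.fixture
def small_fibrous_system(small_fibrous_params):
    return generate_architecture(small_fibrous_params)
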