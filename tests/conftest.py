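import numpy as np
import pytest

from agree3d.primitives import cube, icosphere
from agree3d.synthetic import (
    CohortConfig,
    ObserverModel,
    UterusShapeParams,
    build_cohort,
    generate_true_shape,
)


@pytest.fixture(scope="session")
def unit_cube():
    return cube()


@pytest.fixture(scope="session")
def sphere10():
    return icosphere(10.0, 3)


@pytest.fixture(scope="session")
def sphere20():
    return icosphere(20.0, 3)


@pytest.fixture(scope="session")
def uterus():
    return generate_true_shape(UterusShapeParams(seed=11))


@pytest.fixture(scope="session")
def mini_cohort():
    """2 observers-per-rating cohort, small but exercises every branch."""
    cfg = CohortConfig(rating_counts={1: 1, 2: 2, 3: 2}, n_excluded=1,
                       observer=ObserverModel())
    return build_cohort(cfg, master_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
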