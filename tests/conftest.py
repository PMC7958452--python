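import numpy as np
import pytest

from fieldgan import PhantomSpec, make_anatomy, make_cohort, prepare_cohort


def small_spec(**kw) -> PhantomSpec:
    """Smallest legal phantom grid (must contain a 47^3 patch)."""
    defaults = dict(grid_size=48)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def spec48() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def cohort10(spec48):
    """Ten phantom pairs (5 per class), raw."""
    return make_cohort(spec48, 5, seed=5)


@pytest.fixture(scope="session")
def prepared10(cohort10):
    """The same ten pairs after preprocessing."""
    return prepare_cohort(cohort10)


@pytest.fixture(scope="session")
def anatomy48(spec48):
    return make_anatomy(spec48, "control", np.random.default_rng(0))
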