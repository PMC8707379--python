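import numpy as np
import pytest

from offgrid.examples import fourier_problem, fourier_three_spikes, gaussian_problem
from offgrid.measures import Domain, unit_box, unit_torus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fourier_fixture():
    """Operator + truth for the 1-D Fourier three-spike instance."""
    return fourier_three_spikes()


@pytest.fixture
def fourier_noisy():
    """Factory: seeded noisy BLASSO problem on the Fourier fixture."""

    def make(seed=0, noise=0.02, lam=1.0):
        return fourier_problem(seed=seed, noise=noise, lam=lam)

    return make


@pytest.fixture
def gaussian_noisy():
    """Factory: seeded noisy positive BLASSO problem on the 2-D fixture."""

    def make(seed=0, **kwargs):
        return gaussian_problem(seed=seed, **kwargs)

    return make


@pytest.fixture
def line_domain():
    return Domain(bounds=((0.0, 1.0),))


@pytest.fixture
def torus1():
    return unit_torus(1)


@pytest.fixture
def box2():
    return unit_box(2)
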