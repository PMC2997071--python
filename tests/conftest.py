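import numpy as np
import pytest

from fellersim import (levy, make_named_example)


def component_matrix():
    """Two parameter sets per component constructor, used across tests."""
    return [
        levy.make_brownian(0.0, 1.0),
        levy.make_brownian(0.5, 2.0),
        levy.make_poisson(1.0),
        levy.make_poisson(3.0),
        levy.make_symmetric_stable(0.7, 1.0),
        levy.make_symmetric_stable(1.5, 0.8),
        levy.make_gamma(2.0, 1.0),
        levy.make_gamma(1.0, 2.5),
        levy.make_nig(2.0, 1.0, 1.0, 0.0),
        levy.make_nig(1.0, -0.5, 0.5, 0.3),
        levy.make_meixner(1.0, 1.0, 1.0, 0.0),
        levy.make_meixner(2.0, -0.8, 0.5, 0.2),
    ]


@pytest.fixture(scope="session")
def xi_grid():
    return np.linspace(-5.0, 5.0, 21)


@pytest.fixture(scope="session")
def bpc_family():
    return make_named_example("bpc")


@pytest.fixture(scope="session")
def stable_like_family():
    return make_named_example("stable_like")


@pytest.fixture(scope="session")
def nig_like_family():
    return make_named_example("nig_like")


@pytest.fixture(scope="session")
def meixner_like_family():
    return make_named_example("meixner_like")
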