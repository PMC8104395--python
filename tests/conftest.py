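import numpy as np
import pytest

from v1surround import (
    assign_orientations,
    build_lattice,
    default_parameters,
)


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def lattice_3x3():
    return build_lattice(3, 7, 0.25)


@pytest.fixture(scope="session")
def omap_3x3(lattice_3x3):
    return assign_orientations(lattice_3x3)


@pytest.fixture(scope="session")
def lattice_5x5():
    return build_lattice(5, 7, 0.25)


@pytest.fixture(scope="session")
def omap_5x5(lattice_5x5):
    return assign_orientations(lattice_5x5)


@pytest.fixture(scope="session")
def lattice_full():
    return build_lattice(17, 7, 0.25)


@pytest.fixture(scope="session")
def omap_full(lattice_full):
    return assign_orientations(lattice_full)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210422)
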