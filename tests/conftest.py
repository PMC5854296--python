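import numpy as np
import pytest

import elemcochlea as ec


@pytest.fixture(scope="session")
def params64():
    """Human preset scaled to 64 elements (fast unit-test size)."""
    return ec.CochleaParams(n_elements=64)


@pytest.fixture(scope="session")
def geometry64(params64):
    return ec.build_geometry(params64, "uniform")


@pytest.fixture(scope="session")
def elements64(params64):
    return ec.build_bm_elements(params64)


@pytest.fixture(scope="session")
def fd64(params64, geometry64):
    return ec.assemble_fd_matrix(params64, geometry64.effective_height_mean)


@pytest.fixture(scope="session")
def params128():
    return ec.CochleaParams(n_elements=128)


@pytest.fixture(scope="session")
def model128(params128):
    return ec.CochlearModel.from_params(params128)


@pytest.fixture(scope="session")
def system128(params128):
    geo = ec.build_geometry(params128, "uniform")
    elts = ec.build_bm_elements(params128)
    fd = ec.assemble_fd_matrix(params128, geo.effective_height_mean)
    return ec.assemble_global(params128, elts, fd)


@pytest.fixture
def rng():
    return np.random.default_rng(20180301)
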