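import pytest

from vegroots import GridSpec, ModelParams, build_kernel_approx


@pytest.fixture(scope="session")
def params():
    """Standard (low-altitude) parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def grid1d():
    return GridSpec(Lx=64.0, nx=256)


@pytest.fixture(scope="session")
def grid2d():
    return GridSpec(Lx=12.0, nx=48, Ly=12.0, ny=48)


@pytest.fixture(scope="session")
def approx1d(params, grid1d):
    return build_kernel_approx(params, grid1d)


@pytest.fixture(scope="session")
def approx2d(params, grid2d):
    return build_kernel_approx(params, grid2d)
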