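import pytest

from nicholson_control import BlowfliesParams, StepGrid


@pytest.fixture(scope="session")
def std_params() -> BlowfliesParams:
    """The standard worked-example parameter set (b*u_star ~ 2.708 > 2)."""
    return BlowfliesParams(a=30.0, b=2.0, c=2.0)


@pytest.fixture(scope="session")
def grid_m1() -> StepGrid:
    return StepGrid(1)


@pytest.fixture(scope="session")
def grid_m2() -> StepGrid:
    return StepGrid(2)
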