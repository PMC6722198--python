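import numpy as np
import pytest

from btu.model_core import Domain, DosingParams, DrugParams, default_params


@pytest.fixture(scope="session")
def defaults() -> tuple[DrugParams, DosingParams, Domain]:
    return default_params()


@pytest.fixture(scope="session")
def small_domain() -> Domain:
    """Coarse grid used by most solver tests to keep the suite fast."""
    return Domain(nx=21, ny=21)


@pytest.fixture(scope="session")
def default_run(defaults, small_domain):
    """One shared default simulation on the coarse grid."""
    from btu.pde_solver import default_output_times, simulate

    dp, dos, _ = defaults
    times = default_output_times(2e5, 300)
    return simulate(
        dp, dos, small_domain, t_end=2e5, output_times=times, snapshot_times=times
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
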