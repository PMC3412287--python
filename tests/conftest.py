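import numpy as np
import pytest

from ipwmi import DGPConfig, benchmark_strategies, generate, run_study


@pytest.fixture()
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture()
def small_data():
    """One modest draw from the benchmark generator (N=2000)."""
    return generate(DGPConfig(n=2000), np.random.default_rng(42))


@pytest.fixture(scope="session")
def acceptance_study():
    """The scaled-down strategy comparison shared by the acceptance tests.

    250 replicates of N=1000 with M=10 imputations, all ten strategy rows.
    """
    return run_study(250, DGPConfig(), benchmark_strategies(M=10), seed=0)


@pytest.fixture(scope="session")
def ipwmi_study_1000():
    """1000 replicates of IPW/MI alone, for the variance-calibration check."""
    strats = {"IPW/MI": benchmark_strategies(M=10)["IPW/MI"]}
    return run_study(1000, DGPConfig(), strats, seed=0)
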