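import numpy as np
import pytest

from baselinejm import JointModel
from baselinejm.simulate import SimulationScenario, simulate_joint


@pytest.fixture(scope="session")
def sim_small():
    """One simulated dataset under the standard design (alpha=0.5, sigma_e=0.5)."""
    sc = SimulationScenario(alpha=0.5, sigma_e=0.5)
    long, surv, truth = simulate_joint(sc, seed=11)
    return long, surv, truth


@pytest.fixture(scope="session")
def sim_noisy():
    """Standard design at the largest measurement-error SD (alpha=0.5, sigma_e=1)."""
    sc = SimulationScenario(alpha=0.5, sigma_e=1.0)
    long, surv, truth = simulate_joint(sc, seed=12)
    return long, surv, truth


@pytest.fixture(scope="session")
def joint_fit_small(sim_small):
    long, surv, _ = sim_small
    return JointModel(surv_covariates=("trt", "age")).fit(long, surv)


@pytest.fixture(scope="session")
def joint_fit_noisy(sim_noisy):
    long, surv, _ = sim_noisy
    return JointModel(surv_covariates=("trt", "age")).fit(long, surv)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
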