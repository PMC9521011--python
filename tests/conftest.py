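import numpy as np
import pandas as pd
import pytest

from dnamcvd.io import BetaMatrix
from dnamcvd.simulate import MarkerSpec, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_beta(rng, n=5, p=10, prefix="cg"):
    data = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, p)),
        index=[f"S{i:03d}" for i in range(n)],
        columns=[f"{prefix}{j:07d}" for j in range(p)],
    )
    return BetaMatrix(data)


@pytest.fixture
def small_beta(rng):
    return random_beta(rng)


@pytest.fixture(scope="session")
def planted_cohort():
    """One-marker cohort with 10 identifiable causal CpGs (session-wide)."""
    cfg = SimulationConfig(
        n_samples=800, n_probes=500, seed=7,
        markers={"glucose": MarkerSpec(n_causal_cpgs=10, centre_intercept_sd=0.2,
                                       intercept=4.6)},
        hazard_weights={"glucose": 0.5},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose event times are independent of every marker signal."""
    cfg = SimulationConfig(n_samples=1200, n_probes=60, seed=11,
                           markers={"crp": MarkerSpec(n_causal_cpgs=5, intercept=0.5)},
                           hazard_weights={}, baseline_rate=0.04)
    return simulate_cohort(cfg)
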