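import numpy as np
import pandas as pd
import pytest

from methcna.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale default cohort shared by read-only tests."""
    cfg = SimulationConfig(n_cpg=200, n_genes=100, n_snp=1500, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def beta_frame(rng):
    vals = rng.uniform(0.01, 0.99, size=(12, 6))
    return pd.DataFrame(
        vals,
        index=[f"cg{i:03d}" for i in range(12)],
        columns=[f"S{j}" for j in range(6)],
    )
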