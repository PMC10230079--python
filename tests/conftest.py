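import numpy as np
import pytest

from cseqtl import RunConfig, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired cohort with a few planted effects, shared across tests."""
    cfg = SimConfig(n_individuals=40, n_variants=40, n_genes=8, seed=7,
                    label_proportions={"null": 0.5, "shared": 0.125,
                                       "gain": 0.25, "loss": 0.125})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig(seed=7, n_permutations=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
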