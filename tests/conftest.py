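import pytest

from gliadinkit import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 mutated genes + intact parents + truth (fixed seed)."""
    cfg = SimulationConfig(seed=42, n_genes=20)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def acceptance_cohort():
    """The default 200-gene cohort used for label-recovery checks."""
    cfg = SimulationConfig(seed=11, n_genes=200)
    return cfg, simulate_cohort(cfg)
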