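import pytest

from flreads import AnnotationIndex, SimConfig, simulate_run


@pytest.fixture(scope="session")
def sim_default():
    """One seeded simulation at default study conditions, shared read-only."""
    return simulate_run(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_index(sim_default):
    return AnnotationIndex(sim_default.genes)
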