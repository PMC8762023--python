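import numpy as np
import pytest

from vafscreen.cohort import SimConfig, simulate_cohort, simulate_read_counts
from vafscreen.genemodel import default_gene_model, load_packaged_utr


@pytest.fixture(scope="session")
def model():
    return default_gene_model()


@pytest.fixture(scope="session")
def utr_sequence():
    return load_packaged_utr()


@pytest.fixture(scope="session")
def cohort1_config():
    """The familial discovery-cohort defaults (101 SLE vs 163 non-SLE)."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def cohort1_roster(cohort1_config):
    return simulate_cohort(cohort1_config)


@pytest.fixture(scope="session")
def cohort1_counts(cohort1_config, cohort1_roster):
    rng = np.random.default_rng(cohort1_config.seed)
    roster = simulate_cohort(cohort1_config, rng)
    assert roster.equals(cohort1_roster)
    return simulate_read_counts(roster, ["T635C"], cohort1_config, rng)
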