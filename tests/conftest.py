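import numpy as np
import pytest

from scallopsex import SimConfig, aggregate_replicates, call_samples, relative_expression_table
from scallopsex.synth import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def simulated_cohort(default_config):
    """One default cohort (months 5-13, n=8 each), shared across tests."""
    return simulate_cohort(default_config)


def score_cohort(records):
    """Ct records -> per-sample score/call table via the full pipeline path."""
    agg = aggregate_replicates([r for r in records if r.role == "unknown"])
    rel = relative_expression_table(agg, calibrator="none")
    return call_samples(rel), rel
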