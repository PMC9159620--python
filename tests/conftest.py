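import warnings

import pytest

from translatome import diffexpr as dx
from translatome.simulate import SimConfig, simulate_paired_counts

warnings.filterwarnings("ignore", message="divide by zero")


@pytest.fixture(scope="session")
def paired_truth():
    """Simulated paired dataset under the standard planted-class design."""
    config = SimConfig(seed=11, n_replicates=4)
    return simulate_paired_counts(config)


@pytest.fixture(scope="session")
def analysis(paired_truth):
    paired, _ = paired_truth
    return dx.analyze(paired)


@pytest.fixture(scope="session")
def layer_classification(analysis):
    return dx.classify_layers(analysis)


@pytest.fixture(scope="session")
def te_classification(analysis):
    return dx.classify_te(analysis)
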