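import numpy as np
import pytest

from accidentbn import AccidentRiskModel, default_codebook
from accidentbn.simulate import (
    build_ground_truth,
    default_generator_spec,
    mask_exact,
    sample_survey,
)


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def generator_spec(codebook):
    return default_generator_spec(codebook=codebook)


@pytest.fixture(scope="session")
def truth_bn(generator_spec):
    return build_ground_truth(generator_spec)


@pytest.fixture(scope="session")
def raw_survey(truth_bn):
    """Synthetic analogue of the full field sample: 8892 records with
    exactly 12 accident non-responses."""
    table = sample_survey(truth_bn, 8892, seed=11)
    return mask_exact(table, "V1", 12, seed=12)


@pytest.fixture(scope="session")
def fitted_results(raw_survey):
    """Default end-to-end fit on the synthetic sample (structure
    learned from the data)."""
    return AccidentRiskModel(raw_survey).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
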