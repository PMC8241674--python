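import pytest

from toxfunnel.model_bench import ClassifierSpec, LabeledDataset
from toxfunnel.synthetic import (
    fixture_molecules,
    generate_labeled_library,
    strong_logp_spec,
)


@pytest.fixture(scope="session")
def fixture_mols():
    return fixture_molecules()


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """n=20 synthetic labeled dataset with a strong lipophilicity signal."""
    lib = generate_labeled_library(strong_logp_spec(n=20, seed=3))
    y = lib.labels["cardiotoxicity"]
    return LabeledDataset("cardiotoxicity", lib.X, y, lib.ids)


@pytest.fixture
def rf_spec():
    return ClassifierSpec("random_forest", seed=7)
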