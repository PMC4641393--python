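import pytest

from tmcensus.synthetic_data import SyntheticSpec, generate
from tmcensus.tm_predictor import predict_proteomes


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions at a fixed seed."""
    return generate(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_predictions(default_dataset):
    return predict_proteomes(default_dataset.proteomes)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SyntheticSpec(
        seed=7, n_virus_genomes=6, n_cellular_genomes=3,
        genes_per_virus_mean=40.0, genes_per_cell_mean=80.0,
    ))
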