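import numpy as np
import pandas as pd
import pytest

from natcons.expression import ExpressionMatrix
from natcons.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, tissues, species="mouse", protocol="sense", prefix="ps"):
    """Averaged ExpressionMatrix from an (n, T) array."""
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i:05d}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(ids, name="probeset_id"), columns=list(tissues))
    return ExpressionMatrix(species=species, protocol=protocol, data=data)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_ortholog_groups=40, n_unpaired_probesets=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    write_dataset(small_dataset, out)
    return out
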