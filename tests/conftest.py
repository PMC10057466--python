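import numpy as np
import pandas as pd
import pytest

from redoxsar import (
    DescriptorCalculator,
    dataset_frame,
    load_dataset,
    normalize,
)


@pytest.fixture(scope="session")
def compounds():
    return load_dataset()


@pytest.fixture(scope="session")
def table(compounds):
    return dataset_frame(compounds)


@pytest.fixture(scope="session")
def train_ids(table):
    return list(table.index[table["split"] == "train"])


@pytest.fixture(scope="session")
def test_ids(table):
    return list(table.index[table["split"] == "test"])


@pytest.fixture(scope="session")
def model5_matrix(compounds):
    """Five final-model descriptors for all 30 compounds (seeded conformers)."""
    return DescriptorCalculator(specs="final-model", seed=7).fit().transform(compounds)


@pytest.fixture(scope="session")
def model5_normalized(model5_matrix, train_ids):
    Xn, scaler = normalize(model5_matrix, train_ids)
    return Xn
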