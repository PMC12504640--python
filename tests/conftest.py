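import numpy as np
import pytest

from nichescope.model_core import CellTransformer, ModelConfig
from nichescope.neighborhoods import NeighborhoodConfig, build_neighborhood_index
from nichescope.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """600-cell, 2-section synthetic dataset used by most unit tests."""
    return generate_dataset(SyntheticConfig(cells_per_section=300, n_sections=2, seed=11))


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset.table


@pytest.fixture(scope="session")
def small_index(small_table):
    return build_neighborhood_index(small_table, NeighborhoodConfig(box_width=40.0))


@pytest.fixture(scope="session")
def tiny_model(small_table):
    """Randomly initialized reduced model over the small dataset's panel."""
    return CellTransformer(
        ModelConfig.small(small_table.n_types, small_table.n_genes), seed=5
    )


@pytest.fixture(scope="session")
def small_tokens(tiny_model, small_table):
    return tiny_model.encode_cell_tokens(small_table.log_counts, small_table.cell_type)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
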