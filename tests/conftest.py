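import numpy as np
import pytest

from dpp3qsar.compound_library import (
    build_structures,
    embed_coordinates,
    load_paper_dataset,
)

EMBED_SEED = 2021


@pytest.fixture(scope="session")
def records():
    return load_paper_dataset()


@pytest.fixture(scope="session")
def graphs(records):
    return build_structures(records)


@pytest.fixture(scope="session")
def structures(records, graphs):
    """Embedded 3D structures for all 42 compounds, keyed by id."""
    return {
        r.compound_id: embed_coordinates(graphs[r.compound_id], EMBED_SEED)
        for r in records
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
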