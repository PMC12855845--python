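import numpy as np
import pandas as pd
import pytest

from rhizoecol.io import FeatureTable
from rhizoecol import simulate


def make_table(counts, samples=None, taxa=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=samples, columns=taxa))


@pytest.fixture
def tiny_table():
    return make_table([[5, 0, 3], [1, 3, 0], [2, 2, 2]])


@pytest.fixture(scope="session")
def neutral_community():
    """A small neutrally assembled survey shared across tests."""
    meta = simulate.simulate_metacommunity(60, seed=10)
    table = simulate.simulate_neutral_samples(meta, m=0.5, N=800, n_samples=16, seed=11)
    tree = simulate.simulate_tree(meta.taxon_ids, seed=12)
    metadata = pd.Series(
        ["A"] * 8 + ["B"] * 8, index=table.sample_ids, name="group"
    )
    return meta, table, tree, metadata
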