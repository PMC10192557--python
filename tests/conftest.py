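import numpy as np
import pandas as pd
import pytest

import interevo as ie


@pytest.fixture(scope="session")
def jtt_model():
    return ie.jtt()


@pytest.fixture(scope="session")
def amniote_tree():
    return ie.amniote_fixture_tree()


@pytest.fixture()
def toy_counts():
    """9 cells x 4 genes, 3 clusters, hand-sized for closed-form checks."""
    counts = np.array([
        [5, 0, 1, 4], [6, 1, 0, 3], [4, 0, 2, 4],
        [0, 7, 1, 2], [1, 8, 0, 1], [0, 6, 2, 2],
        [2, 1, 9, 0], [1, 2, 8, 1], [3, 1, 7, 0],
    ])
    cells = [f"c{i}" for i in range(9)]
    meta = pd.DataFrame(
        {"species": "mouse",
         "cluster": ["PV"] * 3 + ["SST"] * 3 + ["VIP"] * 3},
        index=pd.Index(cells, name="cell_id"))
    return ie.CountMatrix(counts=counts, cell_ids=cells,
                          gene_ids=["Ga", "Gb", "Gc", "Gd"], cell_meta=meta)
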