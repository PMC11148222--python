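import numpy as np
import pandas as pd
import pytest

import glupanel as g


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study-sized cohort (35 HGG / 20 MET, 29 genes)."""
    return g.generate_dataset(g.paper_default_config(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    table, clinical = default_dataset
    matrix = g.compute_delta_ct(g.collapse_replicates(table))
    return matrix, clinical


@pytest.fixture
def tiny_ct_frame():
    """Two replicates of one target gene plus TBP in two samples."""
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 4 + ["s2"] * 4,
            "gene": ["GRIA2", "GRIA2", "TBP", "TBP"] * 2,
            "replicate": [1, 2, 1, 2] * 2,
            "ct": [25.0, 25.4, 22.0, 22.2, 28.0, np.nan, 23.0, 23.4],
        }
    )


@pytest.fixture
def tiny_clinical():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "cohort": ["HGG", "MET"],
            "age": [60, 55],
            "sex": ["f", "m"],
            "seizures": [True, False],
        }
    )
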