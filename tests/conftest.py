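import numpy as np
import pandas as pd
import pytest

from mirlink.diffexpr import CountMatrix
from mirlink.network import TargetDatabase
from mirlink.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-truth cohort reused by several stage tests."""
    cfg = SyntheticConfig(n_mrna=1200, n_mirna=200, cluster_size=53, n_true_pairs=80,
                          de_fraction=0.2, db_decoy_count=3000, seed=3)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(30, 8))
    return CountMatrix(counts, [f"f{i}" for i in range(30)],
                       [f"s{j}" for j in range(8)], "mRNA")


@pytest.fixture()
def tiny_db():
    entries = pd.DataFrame({
        "mirna_id": ["miR-a", "miR-a", "miR-b", "miR-c", "miR-b"],
        "gene_id": ["G1", "G2", "G1", "G3", "G4"],
        "source": ["dbX", "dbX", "dbX", "dbY", "dbY"],
        "score": [90.0, 70.0, np.nan, 85.0, 60.0],
    })
    return TargetDatabase(entries, name="tiny")
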