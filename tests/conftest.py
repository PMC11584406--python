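import numpy as np
import pandas as pd
import pytest

from cisconn import synthetic
from cisconn.contacts import PAIR_COLUMNS


def make_pairs(rows):
    """Build a pair table from (chrom1, pos1, strand1, chrom2, pos2, strand2)
    tuples."""
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    return df


@pytest.fixture(scope="session")
def small_truth():
    """Small two-chromosome truth shared by integration tests."""
    return synthetic.build_truth(
        n_genes=20, chrom_sizes={"chr1": 6_000_000, "chr2": 6_000_000},
        samples=synthetic.default_cohort(2, 2, 2), seed=42)


@pytest.fixture(scope="session")
def small_sample_pairs(small_truth):
    """One mucosa sample's simulated contacts on the small truth."""
    return synthetic.simulate_contacts(small_truth, "mucosa_1", 400_000, seed=42)
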