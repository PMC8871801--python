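import numpy as np
import pandas as pd
import pytest

from snpfim.transactions import TransactionDB


@pytest.fixture
def toy_pvals() -> pd.DataFrame:
    """3 SNPs x 4 voxels; at alpha = 0.05 the transactions are
    v1:{s1,s2}, v2:{s2}, v3:{s1}, v4:{s2} (s3 is never significant)."""
    return pd.DataFrame(
        [[0.01, 0.2, 0.05, 0.9], [0.04, 0.03, 0.6, 0.01], [0.5, 0.5, 0.5, 0.5]],
        index=["s1", "s2", "s3"],
        columns=["v1", "v2", "v3", "v4"],
    )


@pytest.fixture
def toy_td5() -> TransactionDB:
    """Five transactions over items a, b, c; at s = 0.6 the frequent sets
    are the three singletons (4/5) and the three pairs (3/5) but not
    {a,b,c} (2/5)."""
    return TransactionDB(
        voxel_ids=["t1", "t2", "t3", "t4", "t5"],
        transactions=[
            {"a", "b", "c"},
            {"a", "b"},
            {"a", "c"},
            {"b", "c"},
            {"a", "b", "c"},
        ],
        alpha=0.05,
    )


def make_random_db(rng: np.random.Generator, max_items: int = 15,
                   max_transactions: int = 60) -> TransactionDB:
    """A random transaction DB for property tests."""
    n_items = rng.integers(2, max_items + 1)
    n_tx = rng.integers(1, max_transactions + 1)
    items = np.array([f"i{j:02d}" for j in range(n_items)])
    density = rng.uniform(0.1, 0.7)
    member = rng.random((n_tx, n_items)) < density
    return TransactionDB(
        voxel_ids=[f"t{k}" for k in range(n_tx)],
        transactions=[frozenset(items[row]) for row in member],
        alpha=0.05,
        items=tuple(items),
    )
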