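"""Random presence/absence site-by-species matrices.

Each site receives a uniform random sample of ``richness`` species from the
tip pool, without replacement and independently across sites.  Fixing the
richness of every site removes richness-driven correlation between diversity
values computed on different trees, which would otherwise mask the effect of
the tree itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_communities", "read_community_csv", "write_community_csv"]


def simulate_communities(pool, n_sites: int = 30, richness: int = 50, seed=None) -> pd.DataFrame:
    """Sites as rows, species as columns, entries in {0, 1}; every row sums to
    exactly ``richness``.  Deterministic given ``seed``."""
    pool = list(pool)
    if richness > len(pool):
        raise ValueError(f"richness {richness} exceeds pool size {len(pool)}")
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_sites, len(pool)), dtype=np.int8)
    for s in range(n_sites):
        mat[s, rng.choice(len(pool), size=richness, replace=False)] = 1
    return pd.DataFrame(
        mat, index=[f"site_{s + 1}" for s in range(n_sites)], columns=pool
    )


def write_community_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="site")


def read_community_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise ValueError("community matrix entries must be 0/1")
    return df.astype(np.int8)
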