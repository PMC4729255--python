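import numpy as np
import pandas as pd
import pytest

from sporocarp import CommunityTable, RegionalPool, TraitTable


@pytest.fixture
def toy_community() -> CommunityTable:
    """Two ST species on two plots in one year."""
    return CommunityTable(pd.DataFrame({
        "plot_id": ["p1", "p1", "p2"],
        "species_id": ["sA", "sB", "sA"],
        "year": [2009, 2009, 2009],
        "count": [5, 2, 1],
    }))


@pytest.fixture
def toy_traits() -> TraitTable:
    """sA, sB saprotrophic (ST); sC ectomycorrhizal (ECM)."""
    return TraitTable(pd.DataFrame({
        "species_id": ["sA", "sB", "sC"],
        "guild": ["ST", "ST", "ECM"],
        "cap_diameter_mm": [10.0, 100.0, 30.0],
    }))


@pytest.fixture
def pool_log123() -> RegionalPool:
    """ST stratum with log10 fruit-body sizes exactly {1, 2, 3}.

    fruit_body_size = d^2, so d = 10^(log10 size / 2).  A one-species ECM
    stratum keeps the pool valid.
    """
    return RegionalPool(pd.DataFrame({
        "species_id": ["st1", "st2", "st3", "ecm1"],
        "guild": ["ST", "ST", "ST", "ECM"],
        "cap_diameter_mm": [10.0 ** 0.5, 10.0, 10.0 ** 1.5, 20.0],
    }))


def random_binary_matrix(rng: np.random.Generator, n_rows: int, n_cols: int,
                         fill: float = 0.3) -> np.ndarray:
    """Random 0/1 matrix without empty rows or columns (regenerated on failure)."""
    while True:
        m = (rng.random((n_rows, n_cols)) < fill).astype(np.int8)
        if m.sum(axis=1).all() and m.sum(axis=0).all():
            return m
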