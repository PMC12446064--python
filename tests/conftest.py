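import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gepcat.data_model import CountMatrix, GEPCatalog
from gepcat.scsim2 import SimParams, simulate_dataset


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """12 cells x 4 features (3 RNA + 1 ADT) with controlled detection."""
    rng = np.random.default_rng(42)
    X = rng.poisson(5, size=(12, 4))
    X[:, 2] = 0
    X[0, 2] = 3
    X[5, 2] = 1  # gene g3 detected in exactly 2 cells
    return CountMatrix(
        values=sp.csr_matrix(X),
        feature_ids=["g1", "g2", "g3", "AB_CD4"],
        cell_ids=[f"c{i}" for i in range(12)],
        cell_meta=pd.DataFrame(
            {"batch": ["a"] * 6 + ["b"] * 6, "sample": "s1"},
            index=[f"c{i}" for i in range(12)],
        ),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with 4 subset + 3 activity GEPs."""
    params = SimParams(n_genes=2000, n_subset_geps=4, n_activity_geps=3, seed=7)
    counts, truth = simulate_dataset(600, params, np.random.default_rng(7))
    return counts, truth, params


@pytest.fixture
def toy_catalog() -> GEPCatalog:
    """4-program catalog over 30 genes with score components and classes."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(30)]
    spectra = pd.DataFrame(
        rng.uniform(0.1, 1.0, size=(4, 30)),
        index=["ProgA", "ProgB", "CellCycle-S", "Doublet-B"],
        columns=genes,
    )
    return GEPCatalog(
        spectra=spectra,
        zscores=pd.DataFrame(
            rng.normal(size=(4, 30)), index=spectra.index, columns=genes
        ),
        program_class=pd.Series(
            ["functional", "activation", "functional", "doublet"], index=spectra.index
        ),
        score_components={"ASA": ["ProgB"], "CellCycle": ["CellCycle-S"]},
    )
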