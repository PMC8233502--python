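import logging

import numpy as np
import pandas as pd
import pytest

import phylokin as pk

logging.disable(logging.INFO)


@pytest.fixture
def three_tip_tree():
    return pk.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    df = pd.DataFrame({
        "species": ["Aa bb", "Cc dd", "Ee ff"],
        "group": "angiosperm",
        "ptype": ["C3", "C3", "C4"],
        "sco": [90.0, 85.0, 78.0],
        "sco_method": "gas_phase",
        "source_id": "gasref",
        "kcatc": [3.0, 3.4, 4.1],
        "kc": [14.0, 16.0, 19.0],
        "ko": [480.0, 470.0, 460.0],
        "krubp": [np.nan, 25.0, np.nan],
    })
    return pk.TraitTable(df, provenance=("fixture",))


@pytest.fixture
def bm_sample():
    """A 50-tip Yule tree with one Brownian trait drawn on it."""
    tree = pk.simulate_yule_tree(50, seed=11)
    C = pk.bm_covariance(tree)
    rng = np.random.default_rng(11)
    L = np.linalg.cholesky(C.to_numpy() + 1e-10 * np.eye(50))
    y = L @ rng.standard_normal(50)
    return tree, C, y
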