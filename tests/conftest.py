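import dendropy
import numpy as np
import pytest

from ecosens import synthetic as syn
from ecosens.config import SyntheticConfig


@pytest.fixture(scope="session")
def hand_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_rows=8, n_cols=8, n_years=6, n_species=20, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> syn.SyntheticBundle:
    return syn.generate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
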