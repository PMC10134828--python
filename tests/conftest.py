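import numpy as np
import pandas as pd
import pytest

from pairfx.growth import MONO, GROWTH_COLUMNS
from pairfx.synth import SyntheticConfig, generate_dataset


def growth_rows(species, partner, carbon, yields):
    return [(species, partner, carbon, i + 1, y) for i, y in enumerate(yields)]


@pytest.fixture
def toy_growth():
    """Hand-built table: monocultures for S1/S2 plus one coculture pair."""
    rows = (
        growth_rows("S1", MONO, "C1", [6.0, 6.0, 6.0])
        + growth_rows("S2", MONO, "C1", [4.0, 4.0, 4.0])
        + growth_rows("S1", "S2", "C1", [2.0, 4.0, 3.0])
        + growth_rows("S2", "S1", "C1", [8.0, 8.0, 8.0])
    )
    return pd.DataFrame(rows, columns=GROWTH_COLUMNS)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic screen shared across tests (8 species, 10 carbons)."""
    return generate_dataset(SyntheticConfig(n_species=8, n_carbons=10, seed=3))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from pairfx.features import aligned_labels, assemble_features

    ds, _ = small_dataset
    X = assemble_features(ds)
    y = aligned_labels(ds, X)
    return X, y


#: modest gradient-boosting hyperparameters for fast test fits
TINY_PARAMS = {"n_estimators": 25, "max_depth": 3, "learning_rate": 0.2}


@pytest.fixture
def tiny_params():
    return dict(TINY_PARAMS)


def make_conserved_twin_dataset():
    """Dataset where S1 and T are phylogenetic twins (distance 0) with
    identical interaction profiles; used for copy-model exactness checks."""
    from pairfx.growth import InteractionDataset

    species = ["P1", "P2", "S1", "T"]
    carbons = ["C1", "C2", "C3"]
    rng = np.random.default_rng(11)
    mono = pd.DataFrame(rng.uniform(1, 5, size=(4, 3)), index=species, columns=carbons)
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0.0)
    d[2, 3] = d[3, 2] = 0.0  # S1 and T are twins
    phylo = pd.DataFrame(d, index=species, columns=species)
    rows = []
    for c in carbons:
        for p in ("P1", "P2"):
            e_on = rng.normal(-0.5, 0.6)
            e_by = rng.normal(-0.5, 0.6)
            for s in ("S1", "T"):
                rows.append((s, p, c, e_on, "positive" if e_on > 0 else "negative"))
                rows.append((p, s, c, e_by, "positive" if e_by > 0 else "negative"))
            e_pp = rng.normal(-0.5, 0.6)
            rows.append((p, "P2" if p == "P1" else "P1", c, e_pp,
                         "positive" if e_pp > 0 else "negative"))
    effects = pd.DataFrame(
        rows, columns=["affected", "affecting", "carbon", "effect", "sign"]
    ).drop_duplicates(subset=["affected", "affecting", "carbon"])
    return InteractionDataset(effects=effects, mono_yields=mono, phylo_dist=phylo)
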