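import numpy as np
import pytest

from combosyn.features import FeatureConfig, Featurizer
from combosyn.simulate import SyntheticConfig, simulate_screen

# A deliberately varied bag of valid drug-like SMILES used across tests.
SMILES_POOL = [
    "C", "CC", "CCO", "c1ccccc1", "c1ccncc1", "c1cncnc1", "COc1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1", "C1CCNCC1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccc2ccccc2c1", "OCC(O)CO",
    "CSCC", "NCCS", "[NH4+]", "CC(=O)[O-]", "FC(F)(F)c1ccccc1",
    "O=C(N)c1ccccc1", "Clc1ccccc1Cl",
]


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def small_config():
    """A reduced feature space used where speed matters more than width."""
    return FeatureConfig(
        cutoffs=(2.0, 4.0),
        descriptors=("RingCount", "NumRotatableBonds", "MolLogP", "fr_methoxy"),
    )


@pytest.fixture(scope="session")
def screen():
    """A seeded synthetic screen shared across tests (read-only)."""
    cfg = SyntheticConfig(n_molecules=24, n_instances=400, seed=7)
    library, df = simulate_screen(cfg)
    return cfg, library, df


@pytest.fixture(scope="session")
def featurized_screen(screen, small_config):
    _, _, df = screen
    fz = Featurizer(small_config)
    X, origin = fz.pair_matrix(df, augment=False)
    y = df["label"].to_numpy(dtype=int)
    return fz, X, y, df


def random_small_smiles(rng, max_atoms=12):
    """Random pick from the pool filtered to at most ``max_atoms`` heavy atoms."""
    from combosyn.chem import parse_smiles

    pool = [s for s in SMILES_POOL if parse_smiles(s).n_atoms <= max_atoms]
    return pool[rng.integers(len(pool))]
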