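import numpy as np
import pandas as pd
import pytest

from esec.chem import AttributeTable, Ensemble, Snapshot, derive_hb_vectors
from esec.synthetic import make_achiral_toy, make_chiral_toy


@pytest.fixture(scope="session")
def toy_ensemble():
    """A 60-frame flexible chiral helix ensemble (R)."""
    return make_chiral_toy(seed=11, n_frames=60)


@pytest.fixture(scope="session")
def achiral_ensemble():
    return make_achiral_toy(seed=7, n_frames=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def simple_attrs():
    """A minimal 6-atom attribute table with all attribute kinds populated."""
    df = pd.DataFrame(
        {
            "mass": [12.0, 1.0, 16.0, 14.0, 12.0, 1.0],
            "charge_ff": [0.1, 0.05, -0.4, -0.3, 0.2, 0.35],
            "charge_gasteiger": [0.08, 0.04, -0.35, -0.25, 0.18, 0.3],
            "polarizability": [1.3, 0.4, 0.9, 1.1, 1.3, 0.4],
            "is_p_orbital": [1, 0, 0, 1, 1, 0],
            "is_hb_donor_h": [0, 0, 0, 0, 0, 1],
            "is_hb_acceptor": [0, 0, 1, 1, 0, 0],
            "is_hydrophobic": [1, 1, 0, 0, 1, 1],
        }
    )
    return derive_hb_vectors(AttributeTable(df))
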