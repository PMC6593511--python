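import numpy as np
import pandas as pd
import pytest

from traitflow.occurrence import OccurrenceMatrix


@pytest.fixture
def toy4_presence() -> pd.DataFrame:
    """4-genome toy: 2 families shared by all, 1 in G1+G2, 1 unique to G3."""
    return pd.DataFrame(
        {
            "G1": [1, 1, 1, 0],
            "G2": [1, 1, 1, 0],
            "G3": [1, 1, 0, 1],
            "G4": [1, 1, 0, 0],
        },
        index=["f_all_1", "f_all_2", "f_g1g2", "f_g3"],
    )


@pytest.fixture
def toy4(toy4_presence) -> OccurrenceMatrix:
    return OccurrenceMatrix(toy4_presence)


@pytest.fixture
def random_matrix() -> OccurrenceMatrix:
    """Seeded random 200 x 13 binary matrix without all-zero rows."""
    rng = np.random.default_rng(7)
    mat = (rng.random((200, 13)) < 0.4).astype(int)
    mat[mat.sum(axis=1) == 0, 0] = 1
    return OccurrenceMatrix(
        pd.DataFrame(
            mat,
            index=[f"fam{i:03d}" for i in range(200)],
            columns=[f"G{j:02d}" for j in range(13)],
        )
    )


@pytest.fixture(scope="session")
def flow_modules():
    from traitflow.pathway_flows import load_flow_roles

    return load_flow_roles()
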