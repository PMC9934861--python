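import numpy as np
import pandas as pd
import pytest

from tcrselect.constants import default_gene_labels
from tcrselect.feature_encoding import build_scheme
from tcrselect.synthetic_data import GenerationModel, default_generation_model, \
    generate_repertoire


@pytest.fixture(scope="session")
def default_model():
    return default_generation_model("alpha")


@pytest.fixture(scope="session")
def alpha_selection_scheme():
    v, j = default_gene_labels("alpha")
    return build_scheme(v, j, include_joint_vj=False)


@pytest.fixture(scope="session")
def small_repertoire(default_model):
    return generate_repertoire(default_model, 5000, seed=7)


def toy_generation_model(length_probs=None, p_a=0.7) -> GenerationModel:
    """Fully enumerable background: 2-letter alphabet, 2 V x 1 J genes,
    short lengths.  Small enough for exhaustive sums."""
    if length_probs is None:
        length_probs = pd.Series({4: 0.6, 5: 0.4})
    prof = np.array([p_a, 1 - p_a])
    return GenerationModel(
        v_probs=pd.Series({"TRAV1": 0.3, "TRAV2": 0.7}),
        j_probs=pd.Series({"TRAJ1": 1.0}),
        length_probs=length_probs,
        aa_left={1: np.array([1.0, 0.0])},
        aa_right={-1: np.array([0.2, 0.8])},
        aa_central=prof,
        alphabet="AC",
    )


@pytest.fixture()
def toy_model():
    return toy_generation_model()
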