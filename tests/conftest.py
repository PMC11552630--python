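import numpy as np
import pandas as pd
import pytest

from cardioslide import PhenotypeParams, RasterImage, generate_slide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_slide():
    """One deterministic 256x256 synthetic nuclei/damage slide pair."""
    params = PhenotypeParams(seed=7, n_nuclei=30)
    nuc, dmg, truth = generate_slide(params, label=1)
    return nuc, dmg, truth, params


def make_score_table(labels, scores, patient_id="P0") -> pd.DataFrame:
    labels = np.asarray(labels)
    return pd.DataFrame({
        "item_path": [f"item{i}.png" for i in range(len(labels))],
        "patient_id": patient_id if isinstance(patient_id, str)
        else list(patient_id),
        "true_label": labels.astype(int),
        "score": np.asarray(scores, dtype=float),
    })


@pytest.fixture
def score_table_factory():
    return make_score_table
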