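import numpy as np
import pandas as pd
import pytest

from exemplarscore.data_model import ClinicalDataset, DataDictionary, Variable
from exemplarscore.synthetic_data import SimulationConfig, simulate_full_study


@pytest.fixture
def tiny_dictionary() -> DataDictionary:
    return DataDictionary([
        Variable("age", "continuous", (0, 100)),
        Variable("episodes", "ordinal", (0, 30)),
        Variable("course", "categorical", ["episodic", "chronic", "mixed"]),
        Variable("psychosis", "binary", ["no", "yes"]),
        Variable("score", "continuous", None),
    ])


@pytest.fixture
def tiny_clinical(tiny_dictionary) -> ClinicalDataset:
    df = pd.DataFrame(
        {
            "site": ["s1", "s1", "s2", "s2"],
            "alda_total": [8.0, 2.0, 9.0, 3.0],
            "response": [1, 0, 1, 0],
            "age": [30.0, 45.0, np.nan, 60.0],
            "episodes": [3.0, 10.0, 5.0, np.nan],
            "course": ["episodic", "chronic", None, "mixed"],
            "psychosis": ["no", "yes", "no", "yes"],
            "score": [0.5, -1.2, 2.0, 0.0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="subject_id"),
    )
    return ClinicalDataset(df, tiny_dictionary)


@pytest.fixture(scope="session")
def small_study():
    """A small but non-degenerate simulated study reused across test modules."""
    config = SimulationConfig(
        n_sites=3, site_sizes=40, n_clinical_features=12,
        n_snps=60, n_causal=12, genotyped_fraction=0.6, seed=11,
    )
    return config, *simulate_full_study(config)


def make_prediction_matrix(p, y, sites=None):
    """Assemble a PredictionMatrix from a raw probability array and labels."""
    from exemplarscore.peso import PredictionMatrix

    p = np.atleast_2d(np.asarray(p, dtype=float))
    n, s = p.shape
    index = pd.Index([f"sub{i:03d}" for i in range(n)], name="subject_id")
    return PredictionMatrix(
        probabilities=pd.DataFrame(
            p, index=index, columns=[f"site{j}" for j in range(s)]
        ),
        y=pd.Series(np.asarray(y, dtype=int), index=index),
        site_of_origin=pd.Series(
            sites if sites is not None else ["site0"] * n, index=index
        ),
    )
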