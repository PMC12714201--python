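import datetime as dt

import numpy as np
import pandas as pd
import pytest

from peradigm.code_embedding import CodeEmbeddingMatrix
from peradigm.ehr_io import CodeFrequencyTable, PatientHistory


def make_history(eid, codes, start=dt.date(2010, 1, 1)):
    return PatientHistory(
        eid, [(start + dt.timedelta(days=i), c) for i, c in enumerate(codes)]
    )


@pytest.fixture
def toy_histories():
    return {
        "A": make_history("A", ["Q612", "N18", "R10"]),
        "B": make_history("B", ["N18", "N18"]),
        "C": make_history("C", ["R10"]),
        "D": make_history("D", []),
    }


@pytest.fixture
def toy_embeddings():
    vecs = {
        "Q612": np.array([1.0, 0.0, 0.0]),
        "N18": np.array([0.0, 1.0, 0.0]),
        "R10": np.array([0.0, 0.0, 1.0]),
    }
    return CodeEmbeddingMatrix(vecs, 3)


@pytest.fixture
def toy_frequencies():
    return CodeFrequencyTable({"Q612": 0.25, "N18": 0.5, "R10": 0.5}, 4)


@pytest.fixture
def toy_covariates():
    rng = np.random.default_rng(0)
    ids = [f"I{i:03d}" for i in range(200)]
    return pd.DataFrame(
        {"age": rng.uniform(40, 70, 200), "sex": rng.integers(0, 2, 200)},
        index=pd.Index(ids, name="eid"),
    )
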