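import numpy as np
import pandas as pd
import pytest

from lipidsig.profiles import ProfileMatrix
from lipidsig.synthetic import study_shaped_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Canonical 16-sample, 40-variable study-shaped dataset (+ truth)."""
    return study_shaped_fixture(seed=0)


@pytest.fixture(scope="session")
def study_profiles(study_fixture):
    return study_fixture[0]


@pytest.fixture(scope="session")
def study_truth(study_fixture):
    return study_fixture[1]


def make_profiles(values: dict, diagnosis: list, kinds=None) -> ProfileMatrix:
    """Small hand-built ProfileMatrix; values maps variable -> list."""
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"s{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {"diagnosis": diagnosis, "tissue": "synovium"}, index=df.index
    )
    kind = None
    if kinds is not None:
        kind = pd.Series(kinds, index=df.columns, name="variable_kind")
    return ProfileMatrix(df, meta, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
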