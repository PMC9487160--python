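import numpy as np
import pandas as pd
import pytest

from elas.cohort import Cohort, Schema
from elas.synthetic import SimSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_schema():
    return Schema(
        id="pid",
        categorical=["stage"],
        continuous=["age", "size"],
        label="event",
    )


@pytest.fixture
def tiny_cohort(tiny_schema):
    features = pd.DataFrame({
        "stage": ["I", "II", "I", "III", "II", "I", "II", "III", "I", "II"],
        "age": [55.0, 62.0, 48.0, 71.0, 59.0, 66.0, 52.0, 69.0, 45.0, 58.0],
        "size": [1.2, 3.4, 0.8, 5.1, 2.2, 2.9, 1.5, 4.4, 0.9, 2.0],
    })
    return Cohort(
        features=features,
        schema=tiny_schema,
        ids=pd.Series([f"P{i}" for i in range(10)], name="pid"),
        labels=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def medium_cohort():
    """200-patient 20%-prevalence cohort with signal, encoded once per session."""
    from elas.cohort import apply_preprocess, fit_preprocess

    cohort, truth = generate_cohort(
        SimSpec(n=200, prevalence=0.2, n_continuous=4, n_categorical=2,
                n_informative=3, effect_size=1.5, seed=7)
    )
    state = fit_preprocess(cohort)
    X = apply_preprocess(cohort, state, standardize=True)
    return X, cohort.labels.astype(int)


class ConstantClassifier:
    """Emits the same probability row for every input (for query tests)."""

    def __init__(self, row=(0.5, 0.5)):
        self.row = np.asarray(row, float)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.tile(self.row, (np.atleast_2d(X).shape[0], 1))


@pytest.fixture
def constant_classifier():
    return ConstantClassifier()
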