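import numpy as np
import pandas as pd
import pytest

from maintainage import CohortConfig, generate_cohort
from maintainage.age import LearnerSpec
from maintainage.prep import ConfoundTable, FeatureMatrix


@pytest.fixture(scope="session")
def linear_spec():
    return LearnerSpec("linear")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_subjects=150, seed=7))


@pytest.fixture()
def toy_features():
    rng = np.random.default_rng(42)
    ids = pd.Index([f"S{i:03d}" for i in range(30)], name="subject_id")
    vals = pd.DataFrame(
        rng.normal(size=(30, 4)), index=ids, columns=["f1", "f2", "f3", "f4"]
    )
    return FeatureMatrix(vals, "gray-matter")


@pytest.fixture()
def toy_confounds(toy_features):
    rng = np.random.default_rng(43)
    return ConfoundTable(
        pd.DataFrame(
            {
                "scanner": rng.binomial(1, 0.3, 30),
                "motion": rng.gamma(4, 0.05, 30),
                "sex": rng.binomial(1, 0.2, 30),
            },
            index=toy_features.subject_ids,
        )
    )
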