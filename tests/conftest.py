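import numpy as np
import pandas as pd
import pytest

from elndi.cohort import (
    OUTCOMES,
    CohortTable,
    GrowthReference,
    LabeledCohort,
    VariableSpec,
)


@pytest.fixture
def growth_ref() -> GrowthReference:
    """Synthetic head-circumference reference: edges exactly at -3..+3 'z'."""
    return GrowthReference(
        measure="head_circumference",
        context="admission",
        sex="male",
        z_edges=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0),
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Six subjects, variables spanning every visit, some missing cells."""
    data = pd.DataFrame(
        {
            "ga_weeks": [28.0, 26.5, 30.0, 27.0, 29.0, 25.0],
            "male": [1.0, 0.0, 1.0, np.nan, 0.0, 1.0],
            "nicu_days": [60.0, 90.0, 45.0, 80.0, np.nan, 100.0],
            "hc_6m": [43.0, 42.0, 44.0, 41.5, 43.5, np.nan],
            "bsid_cog_6m": [98.0, 88.0, 105.0, 92.0, 100.0, 85.0],
            "bsid_mot_6m": [97.0, 85.0, 103.0, 90.0, 99.0, 84.0],
            "bsid_cog_12m": [96.0, 84.0, 104.0, 90.0, 99.0, 82.0],
            "bsid_mot_12m": [95.0, 82.0, 102.0, 88.0, 98.0, 80.0],
            "bsid_cog_24m": [95.0, 80.0, 103.0, 84.0, 98.0, 78.0],
            "bsid_mot_24m": [94.0, 78.0, 101.0, 86.0, 97.0, 75.0],
        },
        index=pd.RangeIndex(6, name="subject_id"),
    )
    dictionary = [
        VariableSpec("ga_weeks", "continuous", "birth", "weeks"),
        VariableSpec("male", "binary", "birth"),
        VariableSpec("nicu_days", "continuous", "hospitalization", "days"),
        VariableSpec("hc_6m", "continuous", "6m", "cm"),
        VariableSpec("bsid_cog_6m", "score", "6m"),
        VariableSpec("bsid_mot_6m", "score", "6m"),
        VariableSpec("bsid_cog_12m", "score", "12m"),
        VariableSpec("bsid_mot_12m", "score", "12m"),
        VariableSpec("bsid_cog_24m", "score", "24m"),
        VariableSpec("bsid_mot_24m", "score", "24m"),
    ]
    return CohortTable(data, dictionary)


def make_labeled(X: pd.DataFrame, y: pd.Series, outcome: str = "CDelay") -> LabeledCohort:
    return LabeledCohort(X, y, OUTCOMES[outcome])


@pytest.fixture
def labeled_random() -> LabeledCohort:
    """100 subjects, 4 noise features, prevalence 0.3 (for split/balance tests)."""
    rng = np.random.default_rng(11)
    X = pd.DataFrame(
        rng.normal(size=(100, 4)),
        columns=[f"x{i}" for i in range(4)],
        index=pd.RangeIndex(100, name="subject_id"),
    )
    y = pd.Series(rng.binomial(1, 0.3, 100), index=X.index)
    y.iloc[:2] = [0, 1]  # guarantee both classes
    return make_labeled(X, y)
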