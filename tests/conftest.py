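import numpy as np
import pandas as pd
import pytest

from spellclust import (
    DEFAULT_GRID,
    CohortTable,
    FeatureTable,
    GeneratorConfig,
    derive_feature_table,
    simulate_cohort,
)
from spellclust.features import FEATURE_COLUMNS


@pytest.fixture
def grid():
    return DEFAULT_GRID


@pytest.fixture
def small_table(grid):
    data = np.array(
        [
            [0, 1, 0, 1, 0],
            [1, 1, 1, 1, 1],
            [0, 0, np.nan, 0, 0],
        ],
        dtype=float,
    )
    return CohortTable(grid=grid, subject_ids=["a", "b", "c"], data=data, name="tiny")


@pytest.fixture
def synthetic_cohort():
    """Complete default cohort with ground truth, shared across tests."""
    table, truth = simulate_cohort(GeneratorConfig(n=1500, seed=7))
    return table, np.array(truth)


@pytest.fixture
def synthetic_features(synthetic_cohort):
    table, truth = synthetic_cohort
    return derive_feature_table(table), truth


def make_feature_table(rows, grid=DEFAULT_GRID, ids=None):
    """Build a FeatureTable from raw six-variable rows (tests helper)."""
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    ids = ids or [f"s{i}" for i in range(len(df))]
    return FeatureTable(subject_ids=ids, data=df, grid=grid)
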