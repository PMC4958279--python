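import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabofp import FeatureTable, StudyDesign, generate_dataset, preprocess
from metabofp.tables import AUTOSCALED, LOG2, RAW

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_table(values, scale=RAW, sample_ids=None, feature_ids=None) -> FeatureTable:
    """Small FeatureTable from a nested list / array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(p)]
    return FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids), scale)


def make_metadata(groups, sample_ids=None, **covariates) -> pd.DataFrame:
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(len(groups))]
    return pd.DataFrame({"sample_id": sample_ids, "group": list(groups), **covariates})


@pytest.fixture(scope="session")
def default_dataset():
    """The default 12-control / 8-case, 289-feature synthetic study (seed 1)."""
    return generate_dataset(StudyDesign(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    """(autoscaled, imputed-raw, fold changes, reports) for the default study."""
    table, metadata, _ = default_dataset
    return preprocess(table, metadata)
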