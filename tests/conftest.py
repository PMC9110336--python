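import warnings

import pandas as pd
import pytest

from mmbm import (
    McmcConfig,
    ModelSpec,
    SyntheticTruth,
    build_dataset,
    fit,
    generate,
    scaled_design,
)
from mmbm.observations import expand_observations


@pytest.fixture(scope="session")
def tiny_truth() -> SyntheticTruth:
    """Small single-covariate design used by several integration tests."""
    return scaled_design(
        n_societies=3, children_per_society=8, obs_per_child=30, dual_code_rate=0.0
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_truth):
    data = generate(tiny_truth, seed=42)
    records = expand_observations(data.observations, data.code_map)
    return data, records


@pytest.fixture(scope="session")
def small_fit(tiny_truth, tiny_dataset):
    """One cached random-effects fit reused across summary/prediction tests."""
    data, records = tiny_dataset
    dataset = build_dataset(records, data.children, data.societies, tiny_truth.spec)
    cfg = McmcConfig(chains=2, iterations=500, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = fit(tiny_truth.spec, dataset, cfg)
    return dataset, result


@pytest.fixture(scope="session")
def intercept_spec() -> ModelSpec:
    return ModelSpec.for_model(1)


@pytest.fixture()
def toy_children() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child_id": ["a", "b"],
            "society_id": ["s1", "s1"],
            "gender": ["girl", "boy"],
            "age_years": [5.0, 14.0],
            "age_label": ["", ""],
            "age_class": ["early", "adolescent"],
        }
    )


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    rows = []
    for cat, n in [("play", 4), ("food_production", 3), ("other", 3)]:
        rows += [("s1", "a", i, cat) for i in range(n)]
    for cat, n in [("childcare", 1), ("other", 4)]:
        rows += [("s1", "b", i, cat) for i in range(n)]
    return pd.DataFrame(
        rows, columns=["society_id", "child_id", "obs_index", "category"]
    )
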