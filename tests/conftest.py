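import numpy as np
import pandas as pd
import pytest

from igaseq.profiles import AsvCountTable, FilterPolicy, validate_sample_metadata
from igaseq.synthetic import PlantedEffect, SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one planted coating and one abundance effect."""
    cfg = SyntheticCohortConfig(
        n_controls=12,
        n_ms=12,
        n_paired=6,
        n_asvs=40,
        seed=20240521,
        planted_coating_effects=(PlantedEffect(0, "control", 0.6),),
        planted_abundance_effects=(PlantedEffect(1, "ms_baseline", 1.5),),
    )
    table, meta, truth = generate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        {
            "s1": [10, 30, 60],
            "s2": [1, 1, 0],
            "s3": [3, 7, 90],
        },
        index=["a1", "a2", "a3"],
    )
    return AsvCountTable(counts)


@pytest.fixture()
def toy_meta():
    rows = []
    for i, sid in enumerate(["s1", "s2", "s3"]):
        rows.append(
            {
                "sample_id": sid,
                "subject_id": f"subj{i}",
                "group": "control",
                "fraction": "presort",
                "timepoint": "baseline",
                "age": 35.0 + i,
                "sex": "female",
                "bmi": 25.0,
                "steroid_use": "none",
            }
        )
    return validate_sample_metadata(pd.DataFrame(rows))


@pytest.fixture()
def default_policy():
    return FilterPolicy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
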