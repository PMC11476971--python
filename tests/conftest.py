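import numpy as np
import pandas as pd
import pytest

from lipidchemo.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with disease and control-only gender effects."""
    cfg = CohortConfig(
        n_sch_m=8, n_sch_f=8, n_c_m=8, n_c_f=8,
        n_features=60, n_disease_features=12, n_gender_features=10,
        missing_rate=0.0, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Full emulated study design: 61 individuals in triplicate, 192 features."""
    return generate_cohort(CohortConfig(seed=7, missing_rate=0.02))


@pytest.fixture()
def replicate_metadata():
    """Six individuals in triplicate, two classes, for partition tests."""
    rows = []
    for cls, n in (("C", 3), ("SCH", 3)):
        for i in range(n):
            for r in range(1, 4):
                rows.append(
                    dict(sample_id=f"{cls}{i}_r{r}", individual_id=f"{cls}{i}",
                         replicate_index=r, class_label=cls,
                         gender="M", batch=1)
                )
    return pd.DataFrame(rows).set_index("sample_id")
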