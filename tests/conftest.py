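import numpy as np
import pandas as pd
import pytest

from tfab.io import attach_derived_scores
from tfab.synthetic import (
    ClinicalCohortSpec,
    NormativeCohortSpec,
    generate_clinical_suite,
    generate_normative,
)


@pytest.fixture(scope="session")
def normative_cohort() -> pd.DataFrame:
    """Default-condition synthetic normative sample (N = 346)."""
    return attach_derived_scores(generate_normative(NormativeCohortSpec(seed=7)))


@pytest.fixture(scope="session")
def clinical_cohort() -> pd.DataFrame:
    """All synthetic clinical groups (N = 40)."""
    return attach_derived_scores(generate_clinical_suite(seed=3))


@pytest.fixture(scope="session")
def mixed_cohort(normative_cohort, clinical_cohort) -> pd.DataFrame:
    return pd.concat([normative_cohort, clinical_cohort], ignore_index=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
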