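import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tcmdetect import (
    SensorModel,
    build_feature_matrix,
    generate_cohort,
    preprocess_cohort,
)


def small_cohort_matrix(exercise: str, n_subjects: int, seed: int, effect_scale: float = 1.0,
                        mode: str = "all"):
    recs, _ = generate_cohort(
        n_subjects=n_subjects, exercises=[exercise], master_seed=seed,
        effect_scale=effect_scale,
    )
    return build_feature_matrix(preprocess_cohort(recs), mode=mode)


@pytest.fixture(scope="session")
def prone_matrix_small():
    """Feature matrix of a 6-subject prone-rocking cohort (36 sets)."""
    return small_cohort_matrix("prone_rocking", n_subjects=6, seed=11)


@pytest.fixture(scope="session")
def prone_matrix_full():
    """Feature matrix of the full 30-subject prone-rocking cohort."""
    return small_cohort_matrix("prone_rocking", n_subjects=30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
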