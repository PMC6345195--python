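import numpy as np
import pytest

from spiraldct import CohortSpec, SpiralParams, generate_cohort, generate_spiral
from spiraldct.classify import Method
from spiraldct.pipeline import feature_matrix_from_samples


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """8 ET + 8 controls with the study's default disturbance presets."""
    samples, manifest = generate_cohort(CohortSpec(n_et=8, n_control=8, seed=11))
    return samples, manifest


@pytest.fixture(scope="session")
def small_cohort_residue_fm(small_cohort):
    samples, _ = small_cohort
    return feature_matrix_from_samples(samples, Method.RESIDUE, 17)


@pytest.fixture(scope="session")
def small_cohort_radius_fm(small_cohort):
    samples, _ = small_cohort
    return feature_matrix_from_samples(samples, Method.RADIUS)


@pytest.fixture(scope="session")
def clean_spiral():
    """A disturbance-free spiral drawing (4096 points at 100 Hz)."""
    return generate_spiral(
        SpiralParams(
            tremor_amp=0.0, drift_amp=0.0, jitter_sd=0.0, duration_s=40.96, seed=1
        )
    )
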