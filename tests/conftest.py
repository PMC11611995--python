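import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import praxmap as pm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def space():
    return pm.PhantomSpace()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for unit tests: fewer patients and controls."""
    cfg = pm.default_config(seed=7, n_patients=12, n_controls=4)
    return pm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """The packaged strong-effect study conditions (fixed seed)."""
    return pm.generate_cohort(pm.default_config(seed=0))


@pytest.fixture(scope="session")
def strong_maps(strong_cohort):
    return pm.cohort_disconnection_maps(
        strong_cohort.lesions, strong_cohort.tractograms, strong_cohort.space
    )


@pytest.fixture(scope="session")
def reference_table():
    return pm.load_reference_table()


@pytest.fixture(scope="session")
def truth_volume(strong_cohort):
    truth = np.zeros(strong_cohort.space.n_voxels, dtype=bool)
    truth[strong_cohort.truth_voxels] = True
    return truth.reshape(strong_cohort.space.shape)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else np.nan
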