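import pytest

from vsgrowth.pipeline import (CohortFeatureSource, compact_grid,
                               run_nested_cv)
from vsgrowth.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort110():
    """The default study-scale synthetic cohort (110 patients, 64%
    growing, seed 2024)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def source110(cohort110):
    return CohortFeatureSource(cohort110)


@pytest.fixture(scope="session")
def full_run(source110):
    """Nested-CV run of the full 404-feature model on the default cohort."""
    return run_nested_cv(source110, grid=compact_grid(), seed=2024)


@pytest.fixture(scope="session")
def cohort20():
    return generate_cohort(CohortConfig(n_patients=20, seed=7))


@pytest.fixture(scope="session")
def source20(cohort20):
    return CohortFeatureSource(cohort20)
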