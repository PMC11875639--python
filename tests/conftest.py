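import numpy as np
import pytest

from gripletrack import cohort, tasks


@pytest.fixture(scope="session")
def coeff_set():
    """Solved coefficient set (5 random lines + repeat line) for the shared seed."""
    return tasks.solve_coefficients(cohort.DEFAULT_TASK_SEED)


@pytest.fixture(scope="session")
def task_set():
    return list(cohort.default_task_set())


@pytest.fixture(scope="session")
def schedule():
    return cohort.default_schedule()


@pytest.fixture(scope="session")
def nc():
    return cohort.nc_preset()


@pytest.fixture(scope="session")
def mci():
    return cohort.mci_preset()


@pytest.fixture(scope="session")
def nc_cohort_lr(nc):
    """Seeded NC cohort (n=40) learning rates via the fast scoring path."""
    return cohort.simulate_cohort_learning_rates(40, nc, 1)


@pytest.fixture(scope="session")
def mci_cohort_lr(mci):
    return cohort.simulate_cohort_learning_rates(28, mci, 1001)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
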