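import numpy as np
import pytest

from softwin.synthetic import CohortSimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Stationary cohort: 300 controls over ~7 months, 14 mutants in 2 batches."""
    return simulate_cohort(
        CohortSimConfig(n_controls=300, n_mutants=14, span_days=200, seed=7)
    )


@pytest.fixture(scope="session")
def drift_cohort():
    """Cohort whose first 90 days have a +3 mean shift and 100x variance."""
    return simulate_cohort(
        CohortSimConfig(
            n_controls=400,
            n_mutants=8,
            span_days=365,
            mutant_batch_days=(280, 287),
            drift_segments=((0, 90, 3.0, 100.0),),
            seed=11,
        )
    )


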