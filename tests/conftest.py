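import numpy as np
import pytest

import opmplace as op
from opmplace.ratemap import GridSpec, RateMap


def make_rate_map(rate, valid=None, dwell=None, bin_size=2.0, smoothed=False):
    """Build a RateMap directly from arrays (test helper)."""
    rate = np.asarray(rate, dtype=float)
    n = rate.shape[0]
    grid = GridSpec(side_length=n * bin_size, bin_size=bin_size)
    if valid is None:
        valid = np.ones_like(rate, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if dwell is None:
        dwell = valid.astype(float)
    return RateMap(
        rate=np.where(valid, rate, np.nan),
        valid=valid,
        grid=grid,
        dwell=np.asarray(dwell, dtype=float),
        smoothed=smoothed,
    )


def random_masked_map(rng, n=20, min_valid=5):
    """Random nonnegative rate map with a random (non-empty) validity mask."""
    rate = rng.uniform(0.0, 10.0, size=(n, n))
    valid = rng.uniform(size=(n, n)) < rng.uniform(0.4, 1.0)
    while valid.sum() < min_valid:
        valid |= rng.uniform(size=(n, n)) < 0.2
    dwell = rng.uniform(0.1, 2.0, size=(n, n)) * valid
    return make_rate_map(rate, valid, dwell)


@pytest.fixture(scope="session")
def long_trajectory():
    """15-min locomotion bout at 30 Hz, the familiarization-trial duration."""
    return op.generate_trajectory(900.0, seed=101)


@pytest.fixture(scope="session")
def sal_session():
    """A 200-unit saline session with known per-transition class probabilities."""
    cohort = op.CohortSpec(
        n_units=200,
        class_probs_t1_t2={
            "stable": 0.40, "unstable": 0.10, "emerging": 0.20,
            "vanishing": 0.10, "inactive": 0.20,
        },
    )
    return op.generate_opm_session(cohort, seed=42)


@pytest.fixture(scope="session")
def sal_session_results(sal_session):
    return op.analyze_session(sal_session)
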