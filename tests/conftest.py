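import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cin4kit import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One 185-sample cohort at the default study conditions."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def large_cohort():
    """~500 samples, for correlation and recovery checks."""
    return generate_cohort(SimConfig(n_per_grade=(167, 167, 166), seed=1))


def random_survival_instance(rng, n=20, beta=0.0, binary=True, round_times=False):
    """Small censored survival data set with an optional covariate effect."""
    if binary:
        x = rng.integers(0, 2, n).astype(float)
        while x.sum() < 2 or x.sum() > n - 2:
            x = rng.integers(0, 2, n).astype(float)
    else:
        x = rng.normal(size=n)
    t_event = rng.exponential(50.0 * np.exp(-beta * x))
    t_cens = rng.uniform(10.0, 120.0, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if round_times:
        time = np.maximum(1.0, np.round(time))
    return x, time, event
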