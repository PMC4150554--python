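import numpy as np
import pandas as pd
import pytest

from hrvrisk import RRSeries, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient cohort with the default group-conditional structure."""
    cfg = default_config(n_total=150, n_positive=15)
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def rr_fixture():
    """A mildly variable 5-min RR series (fixed seed)."""
    rng = np.random.default_rng(7)
    rr = rng.normal(0.85, 0.05, 360).clip(0.5, 1.4)
    return RRSeries(rr)


def make_noise_frame(n, n_pos, p, seed, signal=None, shift=2.0):
    """Feature frame of standard normals; ``signal`` columns get a mean
    shift in the positive class."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"v{i}" for i in range(p)]
    )
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    for col in signal or []:
        X.loc[y == 1, col] += shift
    return X, y
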