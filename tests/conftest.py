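import numpy as np
import pandas as pd
import pytest

from poismr import SimConfig, simulate_cohort
from poismr.validation import onesample_estimate


@pytest.fixture(scope="session")
def cohort20k():
    """Moderate single-exposure cohort reused across one-sample tests."""
    return simulate_cohort(SimConfig(n_participants=20_000, n_snps=15, seed=3))


@pytest.fixture(scope="session")
def onesample_fit(cohort20k):
    """(grs, first stage, second stage, Wald estimate) on cohort20k."""
    return onesample_estimate(cohort20k)


def random_summary(rng, j=30, slope=0.1, sx=0.003, sy_range=(0.005, 0.02)):
    """Random valid-instrument summary-statistics frame."""
    bx = rng.uniform(0.03, 0.15, j)
    sy = rng.uniform(*sy_range, j)
    sx_arr = np.full(j, sx)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i:03d}" for i in range(j)],
            "beta_exposure": rng.normal(bx, sx_arr),
            "se_exposure": sx_arr,
            "beta_outcome": rng.normal(slope * bx, sy),
            "se_outcome": sy,
        }
    )


@pytest.fixture
def summary_factory():
    return random_summary
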