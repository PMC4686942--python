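import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vitdmr import default_config, generate_cohort

CONFOUNDER_NAMES = (
    "sex", "age_at_measure", "bmi", "lag_months", "maternal_education", "u",
)


def null_effects() -> dict:
    """Confounder-effect map with every effect switched off."""
    return {name: (0.0, 0.0) for name in CONFOUNDER_NAMES}


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort under the default study conditions."""
    return generate_cohort(default_config(n=8_000, seed=20_240_101))


@pytest.fixture(scope="session")
def logistic_fixture():
    """A 200-row binary-outcome frame for oracle-equivalence checks."""
    rng = np.random.default_rng(7)
    n = 200
    x = rng.normal(60.0, 20.0, n)
    z = rng.normal(0.0, 1.0, n)
    y = (rng.random(n) < expit(-0.8 + 0.015 * (x - 60.0) + 0.6 * z)).astype(float)
    return pd.DataFrame({"y": y, "x": x, "z": z})


@pytest.fixture(scope="session")
def zip_fixture():
    """A 300-row zero-inflated count frame for oracle-equivalence checks."""
    rng = np.random.default_rng(11)
    n = 300
    x = rng.normal(60.0, 20.0, n)
    lam = 1.6 * np.exp(-0.008 * (x - 60.0))
    counts = rng.poisson(lam)
    dmft = np.where(rng.random(n) < 0.45, 0, counts).astype(float)
    return pd.DataFrame({"dmft": dmft, "x": x})
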