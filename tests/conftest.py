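import numpy as np
import pandas as pd
import pytest

from nptpredict.io import cohort_to_frame
from nptpredict.synthetic import CohortConfig, generate_cohort, generate_diary, generate_pollen_series


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (72 patients) at the default conditions."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    return cohort_to_frame(default_cohort)


@pytest.fixture(scope="session")
def big_cohort_frame():
    """Large cohort for frequency-calibration checks."""
    return cohort_to_frame(generate_cohort(CohortConfig(n_patients=10_000, seed=0)))


@pytest.fixture(scope="session")
def pollen_series():
    return generate_pollen_series(seed=0)


@pytest.fixture(scope="session")
def default_diary(default_cohort, pollen_series):
    return generate_diary(default_cohort, pollen_series, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, start="2016-04-01"):
    """Daily pollen series from a plain list (test helper)."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series([float(v) for v in values], index=idx, name="grains_m3")
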