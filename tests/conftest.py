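import numpy as np
import pandas as pd
import pytest

from maldiprofiler.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_null_config():
    return SyntheticConfig(
        n_cases_per_class=4,
        spots_per_compartment=5,
        mz_min=800.0,
        mz_max=1600.0,
        n_peaks=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_null_dataset(small_null_config):
    return generate_dataset(small_null_config)


@pytest.fixture()
def flat_axis():
    return np.arange(800.0, 1200.0, 1.0)


def gaussian_peak_table(mzs, heights, sigma=2.0):
    return pd.DataFrame({"mz": mzs, "sigma": sigma, "height": heights})


@pytest.fixture()
def peak_table_factory():
    return gaussian_peak_table
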