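from importlib import resources

import pandas as pd
import pytest

from wqfce.indicators import load_scheme, samples_from_dataframe


@pytest.fixture(scope="session")
def customized():
    return load_scheme("customized")


@pytest.fixture(scope="session")
def gb3838():
    return load_scheme("gb3838")


@pytest.fixture(scope="session")
def toy_sites() -> pd.DataFrame:
    """Ten hand-checkable sites: T1-T5 sit exactly at the grade I-V apexes,
    T6-T8 mimic reported polluted sites, T9 has below-detection readings,
    T10 sits exactly between the grade II and III apexes of every indicator."""
    ref = resources.files("wqfce").joinpath("data/toy_sites.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@pytest.fixture(scope="session")
def toy_samples(toy_sites):
    return samples_from_dataframe(toy_sites)
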