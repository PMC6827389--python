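import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from beetlerisk.landscape import LandscapeSeries
from beetlerisk.dataset import build_examples
from beetlerisk.simulate import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_series():
    series, _ = make_fixture("tiny", seed=7)
    return series


@pytest.fixture(scope="session")
def tiny_examples(tiny_series):
    return build_examples(tiny_series)


@pytest.fixture(scope="session")
def separable_series():
    series, _ = make_fixture("separable", seed=3)
    return series


@pytest.fixture(scope="session")
def separable_examples(separable_series):
    return build_examples(separable_series)


def manual_series(
    host, attacks, temperature=None, years=None, volumes=None, cell_size=30.0
) -> LandscapeSeries:
    """Assemble a LandscapeSeries from bare arrays with sensible defaults."""
    host = np.asarray(host, dtype=np.uint8)
    attacks = np.asarray(attacks, dtype=np.uint8)
    if temperature is None:
        temperature = np.full(host.shape, 7.0)
    if years is None:
        years = np.arange(2000, 2000 + attacks.shape[0])
    if volumes is None:
        years_arr = np.asarray(years)
        counts = attacks.sum(axis=(1, 2)).astype(float)
        if len(counts) == len(years_arr):
            vols = counts * 25.0 + np.arange(len(years_arr)) + 1.0
        else:  # deliberately inconsistent input under test
            vols = np.arange(len(years_arr)) + 1.0
        volumes = pd.Series(vols, index=years_arr)
    return LandscapeSeries(
        host=host,
        attacks=attacks,
        temperature=temperature,
        regional_volume=volumes,
        years=np.asarray(years),
        cell_size_m=cell_size,
    )
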