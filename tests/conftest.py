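import numpy as np
import pandas as pd
import pytest

from ricephen import TemperatureSeries, load_species_registry


@pytest.fixture(scope="session")
def registry():
    return load_species_registry()


@pytest.fixture(scope="session")
def nl_model(registry):
    return registry["N_lugens"]


@pytest.fixture(scope="session")
def all_stage_params(registry):
    """All nine (species, stage) parameter sets of the default registry."""
    return [
        (model.species_name, stage)
        for model in registry.values()
        for stage in model.stages
    ]


def make_series(values, start="2021-07-30", height_m=2.0):
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=values.size, freq="h").values
    return TemperatureSeries(height_m=height_m, timestamps=ts, values=values)


@pytest.fixture
def series_factory():
    return make_series
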