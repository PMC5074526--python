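import numpy as np
import pytest

from invrisk.bioclim import derive_bioclim
from invrisk.grids import GridSpec
from invrisk.synthetic_data import VirtualSpecies, generate_climate


@pytest.fixture(scope="session")
def small_spec():
    """30x30 grid of 0.2-degree cells spanning 40-46 N."""
    return GridSpec(n_rows=30, n_cols=30, x_min=-120.0, y_min=40.0, cell_size=0.2)


@pytest.fixture(scope="session")
def small_scenario(small_spec):
    return generate_climate(spec=small_spec, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    """Baseline bioclim stack on the small grid."""
    return derive_bioclim(small_scenario.baseline)


@pytest.fixture(scope="session")
def small_future_stack(small_scenario):
    return derive_bioclim(small_scenario.future)


@pytest.fixture(scope="session")
def species():
    return VirtualSpecies()
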