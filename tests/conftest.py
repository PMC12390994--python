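import numpy as np
import pytest

from panicov import synthetic_data as sd
from panicov.reference_params import treatment_params


@pytest.fixture(scope="session")
def ref_params():
    """The zero-nitrogen 2023 field parameter set used as a canonical truth."""
    return treatment_params("23-F-0N")


@pytest.fixture(scope="session")
def small_image_config(ref_params):
    """A small canvas so image tests stay fast; geometry math is size-free."""
    return sd.ScenarioConfig(true_params=ref_params, image_size=96, seed=0)


@pytest.fixture(scope="session")
def yield_table_200():
    """Default synthetic yield table at the standard scenario size (200 plots)."""
    params = sd.sample_params_envelope(200, seed=42)
    return sd.generate_yield_table(params, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
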