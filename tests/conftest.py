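import numpy as np
import pytest

from lupuskit.vep_damage import PredictorCatalog


@pytest.fixture(scope="session")
def catalog() -> PredictorCatalog:
    return PredictorCatalog.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)
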