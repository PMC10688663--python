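import numpy as np
import pytest

from lwseg.synthfield import FieldSimConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: easy-contrast generator settings used by the training smoke tests: clean
#: water background, no glint, slightly larger plants
EASY_FIELD = dict(tile_size=64, noise_sd=0.01, glint_rate=0.0, plant_radius=3.0)


@pytest.fixture(scope="session")
def easy_batch():
    """8 training tiles + 1 validation tile of easy synthetic paddy."""
    recs = make_dataset(FieldSimConfig(seed=7, **EASY_FIELD), 9,
                        density_regime="medium", plant_radius=3.0)
    for r in recs[:8]:
        r.split = "train"
    recs[8].split = "validation"
    return recs


@pytest.fixture(scope="session")
def easy_dataset_100():
    """100 easy synthetic tiles for the short end-to-end training run."""
    return make_dataset(FieldSimConfig(seed=11, **EASY_FIELD), 100,
                        density_regime="medium", plant_radius=3.0)
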