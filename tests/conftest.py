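import numpy as np
import pytest

from coughkit.audio_core import stream_rng
from coughkit.experiment import FeatureCache
from coughkit.synth_fixtures import FixtureConfig, gen_corpus


@pytest.fixture(scope="session")
def shared_cache():
    """One feature cache for the whole session: augmentation + extraction
    are deterministic, so blocks are safely shared across tests."""
    return FeatureCache()


@pytest.fixture(scope="session")
def small_corpus():
    """A cheap corpus (12 coughs, 4 events/type) for structural tests."""
    return gen_corpus(FixtureConfig(seed=7, n_coughs=12, n_per_noise_type=4,
                                    noise_mean_s=0.7, noise_sd_s=0.15))


@pytest.fixture()
def rng():
    return stream_rng(123, "tests")
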