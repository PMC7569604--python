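import numpy as np
import pytest

from whitefly_phenology import apply_adjustment, default_bundle


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def adjusted(bundle):
    return apply_adjustment(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
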