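import numpy as np
import pytest

from affetds.nn import CnnConfig, SmallCnn
from affetds.preprocessing import PreprocessConfig
from affetds.synthetic import CorpusParams, PhantomParams, build_default_corpus, stratified_split


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom224():
    from affetds.synthetic import generate_phantom

    return generate_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 40-sample corpus with splits, shared across tests (session-scoped)."""
    params = CorpusParams(n_total=40)
    manifest = build_default_corpus(seed=3, params=params)
    return stratified_split(manifest, seed=3)


@pytest.fixture(scope="session")
def tiny_cnn():
    """A small untrained CNN on 32x32 inputs (cheap gradient source)."""
    return SmallCnn(CnnConfig(input_size=32, conv_widths=(4, 8), fc_width=16, seed=0))


@pytest.fixture(scope="session")
def preprocess_config():
    return PreprocessConfig()
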