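import numpy as np
import pytest

from pestimix import (
    DesignConfig,
    GenerativeParams,
    build_default_panel,
    build_design,
)


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def default_design(panel):
    return build_design(panel, DesignConfig(), seed=11)


@pytest.fixture(scope="session")
def paper_params():
    return GenerativeParams.preset("paper_like", seed=5)


@pytest.fixture(scope="session")
def null_params():
    return GenerativeParams.preset("null", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
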