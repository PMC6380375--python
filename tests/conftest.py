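import numpy as np
import pytest

from scalpmap import eegsim, stmap


@pytest.fixture(scope="session")
def montage():
    return eegsim.load_montage()


@pytest.fixture(scope="session")
def grid(montage):
    return stmap.project_montage(montage)


@pytest.fixture(scope="session")
def templates(montage):
    return eegsim.default_templates(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
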