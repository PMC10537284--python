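import numpy as np
import pytest
from PIL import Image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def png_factory(tmp_path):
    """Write a small uint8 array as a PNG and return its path."""

    def make(arr, name="img.png"):
        path = tmp_path / name
        Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
        return path

    return make
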