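import numpy as np
import pytest

from ptxmode.usim import DomainParams, MmodeSpec, generate_mmode


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair():
    """A seashore/barcode image pair at the same seed in the phantom domain."""
    dom = DomainParams()
    neg = generate_mmode(MmodeSpec(ptx_positive=False, seed=1), dom)
    pos = generate_mmode(MmodeSpec(ptx_positive=True, seed=1), dom)
    return neg, pos


def sub_pleural(image):
    """Pixel block strictly below the pleural-line band."""
    start = image.pleural_row + max(2, image.spec.height_px // 48)
    return image.pixels[start:, :]


def lag1_column_diff(image):
    """Mean absolute lag-1 column difference below the pleural line."""
    return float(np.abs(np.diff(sub_pleural(image), axis=1)).mean())
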