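import numpy as np
import pytest

from mglia.mask import CellMask
from skimage.draw import disk as _disk


def make_disc(radius: int, pad: int = 10, calibration: float = 1.0) -> CellMask:
    side = 2 * (radius + pad)
    m = np.zeros((side, side), dtype=bool)
    rr, cc = _disk((side // 2, side // 2), radius, shape=m.shape)
    m[rr, cc] = True
    return CellMask(m, calibration)


def sierpinski_carpet(depth: int) -> np.ndarray:
    a = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(a)
        a = np.block([[a, a, a], [a, z, a], [a, a, a]])
    return a


@pytest.fixture
def disc50() -> CellMask:
    return make_disc(50)


@pytest.fixture
def square10() -> CellMask:
    m = np.zeros((14, 14), dtype=bool)
    m[2:12, 2:12] = True
    return CellMask(m, 1.0)


@pytest.fixture
def plus_sign() -> np.ndarray:
    """Two 21-px, 1-px-wide strokes crossing at the center."""
    m = np.zeros((31, 31), dtype=bool)
    m[5:26, 15] = True
    m[15, 5:26] = True
    return m


@pytest.fixture
def l_path() -> np.ndarray:
    """Two 11-pixel orthogonal arms sharing the corner pixel."""
    m = np.zeros((20, 20), dtype=bool)
    m[0:11, 0] = True
    m[10, 0:11] = True
    return m
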