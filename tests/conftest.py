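import numpy as np
import pytest

from rotomorph import RMPConfig, StructuringElement, make_line_se


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_image(rng):
    """A 16x16 8-bit-valued test image."""
    return rng.integers(0, 256, size=(16, 16)).astype(np.float64)


@pytest.fixture
def se_square3():
    """Flat 3x3 square structuring element."""
    offs = [(s, t) for s in (-1, 0, 1) for t in (-1, 0, 1)]
    return StructuringElement(np.array(offs))


@pytest.fixture
def se_line41():
    return make_line_se(41)


@pytest.fixture
def config8():
    return RMPConfig(n_directions=8)


def random_se(rng, max_extent=2, max_size=6):
    """A random small flat SE guaranteed to contain the origin."""
    k = int(rng.integers(1, max_size))
    offs = {(0, 0)}
    while len(offs) < k + 1:
        offs.add(
            (int(rng.integers(-max_extent, max_extent + 1)),
             int(rng.integers(-max_extent, max_extent + 1)))
        )
    return StructuringElement(np.array(sorted(offs)))


def brute_dilate(f, se):
    """Direct double-loop evaluation of grayscale dilation."""
    h, w = f.shape
    out = np.empty_like(f)
    for x in range(h):
        for y in range(w):
            vals = [
                f[x - s, y - t] + b
                for (s, t), b in zip(se.offsets, se.heights)
                if 0 <= x - s < h and 0 <= y - t < w
            ]
            out[x, y] = max(vals)
    return out


def brute_erode(f, se):
    """Direct double-loop evaluation of grayscale erosion."""
    h, w = f.shape
    out = np.empty_like(f)
    for x in range(h):
        for y in range(w):
            vals = [
                f[x + s, y + t] - b
                for (s, t), b in zip(se.offsets, se.heights)
                if 0 <= x + s < h and 0 <= y + t < w
            ]
            out[x, y] = min(vals)
    return out
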