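"""Image reading and writing.

PGM (binary P5, 8- and 16-bit) is handled natively so that 16-bit
round-trips are exact; PNG and TIFF go through imageio.  Color inputs
are reduced to a single channel (green by default — the conventional
choice for vessel contrast in retinal fundus images).

Real-valued pipeline outputs are quantized with round-half-even and
clipped into the target bit depth at write time; clipping is logged.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .morphology import as_image

__all__ = ["read_image", "write_image"]

logger = logging.getLogger("rotomorph")

_CHANNELS = {"red": 0, "green": 1, "blue": 2}
_SUPPORTED = {".pgm", ".png", ".tif", ".tiff"}


def _read_pgm(path: Path) -> np.ndarray:
    data = path.read_bytes()
    # header: magic, width, height, maxval — whitespace/comment separated
    tokens = []
    pos = 0
    while len(tokens) < 4:
        m = re.compile(rb"\s*(#[^\n]*\n|\S+)").match(data, pos)
        if m is None:
            raise ValueError(f"{path}: truncated PGM header")
        pos = m.end()
        tok = m.group(1)
        if not tok.startswith(b"#"):
            tokens.append(tok)
    magic, width, height, maxval = tokens
    if magic != b"P5":
        raise ValueError(f"{path}: not a binary (P5) PGM file")
    width, height, maxval = int(width), int(height), int(maxval)
    dtype = np.dtype(">u2") if maxval > 255 else np.uint8
    pos += 1  # single whitespace byte after maxval
    raster = np.frombuffer(data, dtype=dtype, count=height * width, offset=pos)
    return raster.reshape(height, width).astype(np.float64)


def _write_pgm(image: np.ndarray, path: Path, maxval: int) -> None:
    dtype = np.dtype(">u2") if maxval > 255 else np.uint8
    header = f"P5\n{image.shape[1]} {image.shape[0]}\n{maxval}\n".encode()
    path.write_bytes(header + image.astype(dtype).tobytes())


def read_image(path, channel: str = "green") -> np.ndarray:
    """Read a grayscale image (PGM/PNG/TIFF) as a 2-D float64 array.

    Color images are reduced by the configured channel selection; the
    choice is logged.  Integer bit depth is preserved in the value
    range (a 16-bit input keeps its 0–65535 values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix not in _SUPPORTED:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
    if suffix == ".pgm":
        return _read_pgm(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        idx = _CHANNELS.get(channel)
        if idx is None or arr.shape[2] <= idx:
            raise ValueError(f"cannot select channel {channel!r} from {path}")
        logger.info("reduced color image %s to %s channel", path, channel)
        arr = arr[:, :, idx]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got {arr.shape}")
    return arr.astype(np.float64)


def write_image(image, path, bit_depth: int = 8) -> None:
    """Quantize (round-half-even), clip to the bit depth, and write.

    Out-of-range values are clipped and the clip count logged as a
    warning.
    """
    f = as_image(image)
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxval = (1 << bit_depth) - 1
    q = np.rint(f)
    n_clipped = int(np.count_nonzero((q < 0) | (q > maxval)))
    if n_clipped:
        logger.warning("clipped %d out-of-range pixels writing %s", n_clipped, path)
    q = np.clip(q, 0, maxval)
    suffix = path.suffix.lower()
    if suffix == ".pgm":
        _write_pgm(q, path, maxval)
    elif suffix in _SUPPORTED:
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        iio.imwrite(path, q.astype(dtype))
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
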