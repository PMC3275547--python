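"""Grayscale mathematical morphology primitives.

Images are plain 2-D numpy arrays of finite scalars (``float64``
internally); a structuring element (SE) is a set of integer pixel
offsets with an optional additive height per offset (all zero for the
flat elements the enhancement pipeline uses).

Border policy: the extremum at each pixel runs only over SE offsets
whose source coordinate lies inside the image — equivalent to padding
with -inf for dilation and +inf for erosion.  Near the border the
window simply shrinks; no reflected or replicated samples are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructuringElement",
    "make_line_se",
    "make_disk_se",
    "dilation",
    "erosion",
    "opening",
    "closing",
    "as_image",
]


def as_image(image) -> np.ndarray:
    """Coerce *image* to a validated 2-D float64 array.

    Raises ``ValueError`` for empty, non-2-D, or non-finite input.
    """
    f = np.asarray(image, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {f.shape}")
    if f.size == 0:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(f)):
        raise ValueError("image contains non-finite values")
    return f


@dataclass(frozen=True)
class StructuringElement:
    """A set of integer (row, col) offsets with per-offset heights.

    ``offsets`` has shape (k, 2); ``heights`` has shape (k,) and is all
    zero for a flat element.  The origin convention is offset (0, 0);
    an SE need not contain the origin, but the elements built by
    :func:`make_line_se` and :func:`make_disk_se` always do.
    """

    offsets: np.ndarray
    heights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        off = np.atleast_2d(np.asarray(self.offsets, dtype=np.intp))
        if off.size == 0:
            raise ValueError("structuring element must be nonempty")
        if off.ndim != 2 or off.shape[1] != 2:
            raise ValueError("offsets must be an (k, 2) array of (row, col)")
        if len(np.unique(off, axis=0)) != len(off):
            raise ValueError("offsets must be distinct")
        h = self.heights
        h = np.zeros(len(off)) if h is None else np.asarray(h, dtype=np.float64)
        if h.shape != (len(off),):
            raise ValueError("heights must match offsets one-to-one")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "heights", h)

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.heights == 0))

    def reflect(self) -> "StructuringElement":
        """The reflected element B̌: every offset negated, heights kept."""
        return StructuringElement(-self.offsets, self.heights.copy())


def _check_odd(size: int, what: str) -> int:
    size = int(size)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"{what} must be a positive odd integer, got {size}")
    return size


def make_line_se(length: int, angle: float = 0.0) -> StructuringElement:
    """Flat line-segment SE of `length` pixels, width 1, centred origin.

    ``angle`` is in degrees, 0 = horizontal.  The rotational pipeline
    always uses angle 0 and rotates the image instead; nonzero angles
    rasterize the segment by rounding points on the continuous line.
    """
    length = _check_odd(length, "line length")
    half = length // 2
    t = np.arange(-half, half + 1)
    theta = np.deg2rad(angle)
    rows = np.rint(-t * np.sin(theta)).astype(np.intp)
    cols = np.rint(t * np.cos(theta)).astype(np.intp)
    offsets = np.unique(np.stack([rows, cols], axis=1), axis=0)
    return StructuringElement(offsets)


def make_disk_se(diameter: int) -> StructuringElement:
    """Flat disk SE: all offsets (s, t) with s² + t² ≤ (diameter/2)²."""
    diameter = _check_odd(diameter, "disk diameter")
    r = diameter / 2.0
    half = diameter // 2
    s, t = np.mgrid[-half : half + 1, -half : half + 1]
    keep = s * s + t * t <= r * r
    offsets = np.stack([s[keep], t[keep]], axis=1)
    return StructuringElement(offsets)


def _shifted_extremum(f: np.ndarray, se: StructuringElement, sign: int) -> np.ndarray:
    """Max (sign=+1, dilation) or min (sign=-1, erosion) over SE offsets.

    Dilation samples f(x-s, y-t) + B(s,t); erosion samples
    f(x+s, y+t) - B(s,t).  Both reduce to accumulating shifted copies.
    Out-of-bounds samples are excluded from the extremum.
    """
    h, w = f.shape
    out = np.full((h, w), -np.inf if sign > 0 else np.inf)
    acc = np.maximum if sign > 0 else np.minimum
    for (s, t), b in zip(se.offsets, se.heights):
        # dilation: out(x,y) op= f(x-s, y-t)+b  → source index x-s valid
        # erosion:  out(x,y) op= f(x+s, y+t)-b  → same slices with s,t negated
        ds, dt = (int(s), int(t)) if sign > 0 else (-int(s), -int(t))
        x0, x1 = max(0, ds), min(h, h + ds)
        y0, y1 = max(0, dt), min(w, w + dt)
        if x0 >= x1 or y0 >= y1:
            continue
        src = f[x0 - ds : x1 - ds, y0 - dt : y1 - dt]
        acc(out[x0:x1, y0:y1], src + sign * b, out=out[x0:x1, y0:y1])
    if not np.all(np.isfinite(out)):
        raise ValueError(
            "structuring element leaves some pixels with no in-bounds sample"
        )
    return out


def dilation(image, se: StructuringElement) -> np.ndarray:
    """Grayscale dilation δ_B(f): pixelwise max of f(x−s, y−t) + B(s,t)."""
    return _shifted_extremum(as_image(image), se, +1)


def erosion(image, se: StructuringElement) -> np.ndarray:
    """Grayscale erosion ε_B(f): pixelwise min of f(x+s, y+t) − B(s,t)."""
    return _shifted_extremum(as_image(image), se, -1)


def opening(image, se: StructuringElement) -> np.ndarray:
    """Opening γ_B(f) = δ_B(ε_B(f)); removes bright structures smaller than B."""
    return dilation(erosion(image, se), se)


def closing(image, se: StructuringElement) -> np.ndarray:
    """Closing ϕ_B(f) = ε_B(δ_B(f)); fills dark structures smaller than B."""
    return erosion(dilation(image, se), se)
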