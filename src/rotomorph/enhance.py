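"""Contrast modification and the full enhancement pipeline.

The proposed two-step method is: selective feature extraction by the
rotational top-hat filter (:func:`rotomorph.rmp.feature_extract`),
then contrast modification of the feature image by global histogram
equalization (HE) followed by linear contrast stretching (LCS).

The module also provides the standard comparison methods — HE and LCS
applied directly, unsharp masking (USM), multiscale retinex (MSR) and
contrast-limited adaptive histogram equalization (CLAHE) — at the
parameter settings used throughout the evaluation (USM: Gaussian
radius 10 px, weight 0.7; MSR: σ = 5, 50, 150 px with weights 1/3;
CLAHE: 15×15 blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphology import StructuringElement, as_image
from .rmp import RMPConfig, feature_extract

__all__ = [
    "EnhanceParams",
    "histogram_equalize",
    "linear_stretch",
    "unsharp_mask",
    "multiscale_retinex",
    "clahe",
    "enhance",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the contrast-modification stage and comparison methods."""

    levels: int = 256
    out_range: tuple[float, float] = (0.0, 255.0)
    usm_radius: float = 10.0
    usm_weight: float = 0.7
    msr_sigmas: tuple[float, ...] = (5.0, 50.0, 150.0)
    msr_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    clahe_block: int = 15
    clahe_clip: float = 2.0

    def __post_init__(self):
        if int(self.levels) < 2:
            raise ValueError("levels must be >= 2")
        lo, hi = self.out_range
        if not lo < hi:
            raise ValueError("out_range must have min < max")
        if len(self.msr_sigmas) != len(self.msr_weights):
            raise ValueError("msr_sigmas and msr_weights must have equal length")
        if abs(sum(self.msr_weights) - 1.0) > 1e-9:
            raise ValueError("msr_weights must sum to 1")


def _quantize(f: np.ndarray, levels: int) -> np.ndarray:
    """Affine pre-quantization of a real-valued image to 0 … levels−1."""
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.zeros(f.shape, dtype=np.intp)
    q = np.rint((levels - 1) * (f - lo) / (hi - lo))
    return q.astype(np.intp)


def _he_mapping(hist: np.ndarray, levels: int) -> np.ndarray:
    """CDF-based intensity mapping T(v) = (levels−1)·CDF(v), unrounded."""
    cdf = np.cumsum(hist) / hist.sum()
    return (levels - 1) * cdf


def histogram_equalize(image, levels: int = 256) -> np.ndarray:
    """Global histogram equalization over `levels` bins.

    The real-valued input is affinely quantized to ``levels`` bins,
    then remapped by T(v) = round((levels−1)·CDF(v)).  The mapping is
    monotone non-decreasing, so pixel rank order is preserved.  A
    constant image is returned unchanged (the mapping is degenerate).
    """
    f = as_image(image)
    if int(levels) < 2:
        raise ValueError("levels must be >= 2")
    levels = int(levels)
    if f.min() == f.max():
        return f.copy()
    q = _quantize(f, levels)
    hist = np.bincount(q.ravel(), minlength=levels)
    t = np.rint(_he_mapping(hist, levels))
    return t[q]


def linear_stretch(image, out_range: tuple[float, float] = (0.0, 255.0)) -> np.ndarray:
    """Linear contrast stretching: affine map of [min, max] onto out_range.

    A constant image maps to ``out_range[0]`` everywhere (the affine
    map is degenerate; no division by zero).
    """
    f = as_image(image)
    lo, hi = float(out_range[0]), float(out_range[1])
    if not lo < hi:
        raise ValueError("out_range must have min < max")
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full(f.shape, lo)
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def unsharp_mask(
    image,
    radius: float = 10.0,
    weight: float = 0.7,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Unsharp masking: (f − w·G_σ(f)) / (1 − w) with σ = radius.

    This normalization leaves flat regions at their original level
    (constants are fixed points).  The result is clipped to
    ``value_range``.
    """
    f = as_image(image)
    if not 0.0 <= weight < 1.0:
        raise ValueError("weight must be in [0, 1)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    blurred = ndimage.gaussian_filter(f, sigma=radius)
    out = (f - weight * blurred) / (1.0 - weight)
    return np.clip(out, value_range[0], value_range[1])


def multiscale_retinex(
    image,
    sigmas: tuple[float, ...] = (5.0, 50.0, 150.0),
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3),
    out_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Multiscale retinex: weighted log-domain difference of f and its blurs.

    r = Σ_k w_k · [log(f+1) − log(G_{σ_k}(f)+1)], linearly stretched to
    ``out_range`` for display.  Input values must be non-negative.
    """
    f = as_image(image)
    if len(sigmas) != len(weights):
        raise ValueError("sigmas and weights must have equal length")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if f.min() < 0:
        raise ValueError("retinex requires non-negative image values")
    log_f = np.log1p(f)
    r = np.zeros_like(f)
    for sigma, w in zip(sigmas, weights):
        r += w * (log_f - np.log1p(ndimage.gaussian_filter(f, sigma=sigma)))
    return linear_stretch(r, out_range)


def _clip_redistribute(hist: np.ndarray, clip: float) -> np.ndarray:
    """Clip a histogram at clip × (uniform bin height), redistribute excess."""
    if not np.isfinite(clip):
        return hist.astype(np.float64)
    limit = clip * hist.sum() / len(hist)
    clipped = np.minimum(hist, limit).astype(np.float64)
    excess = hist.sum() - clipped.sum()
    return clipped + excess / len(hist)


def clahe(image, block: int = 15, clip: float = 2.0, levels: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is tiled into ``block``×``block`` regions; each tile's
    histogram is clipped at ``clip`` times the uniform bin height with
    the excess redistributed evenly, and the per-tile CDF mappings are
    bilinearly interpolated between tile centres.  With a single tile
    covering the whole image and ``clip = inf`` this reduces exactly to
    global histogram equalization.
    """
    f = as_image(image)
    block = int(block)
    if block < 2:
        raise ValueError("block must be >= 2")
    h, w = f.shape
    if block > h or block > w:
        raise ValueError(f"block {block} larger than image {h}x{w}")
    levels = int(levels)
    if f.min() == f.max():
        return f.copy()
    q = _quantize(f, levels)

    ny, nx = -(-h // block), -(-w // block)
    y_edges = np.minimum(np.arange(ny + 1) * block, h)
    x_edges = np.minimum(np.arange(nx + 1) * block, w)
    centers_y = (y_edges[:-1] + y_edges[1:] - 1) / 2.0
    centers_x = (x_edges[:-1] + x_edges[1:] - 1) / 2.0

    maps = np.empty((ny, nx, levels))
    for i in range(ny):
        for j in range(nx):
            tile = q[y_edges[i] : y_edges[i + 1], x_edges[j] : x_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=levels)
            maps[i, j] = _he_mapping(_clip_redistribute(hist, clip), levels)

    # fractional tile-grid coordinate of each pixel, clamped at the rim
    gy = np.interp(np.arange(h), centers_y, np.arange(ny))
    gx = np.interp(np.arange(w), centers_x, np.arange(nx))
    i0 = np.clip(np.floor(gy).astype(np.intp), 0, ny - 1)
    j0 = np.clip(np.floor(gx).astype(np.intp), 0, nx - 1)
    i1 = np.minimum(i0 + 1, ny - 1)
    j1 = np.minimum(j0 + 1, nx - 1)
    wy = (gy - i0)[:, None]
    wx = (gx - j0)[None, :]

    i0c, i1c = i0[:, None], i1[:, None]
    j0r, j1r = j0[None, :], j1[None, :]
    out = (
        (1 - wy) * (1 - wx) * maps[i0c, j0r, q]
        + (1 - wy) * wx * maps[i0c, j1r, q]
        + wy * (1 - wx) * maps[i1c, j0r, q]
        + wy * wx * maps[i1c, j1r, q]
    )
    return np.rint(out)


def enhance(
    image,
    se: StructuringElement,
    config: RMPConfig | None = None,
    params: EnhanceParams | None = None,
    return_intermediates: bool = False,
):
    """The full two-step enhancement pipeline.

    Step 1 extracts features smaller than the SE with the rotational
    top-hat filter; step 2 boosts their contrast with HE followed by
    LCS.  Returns the enhanced image spanning exactly ``out_range``,
    or (enhanced, feature image, equalized image) with
    ``return_intermediates``.
    """
    params = params or EnhanceParams()
    feat = feature_extract(image, se, config)
    eq = histogram_equalize(feat, params.levels)
    out = linear_stretch(eq, params.out_range)
    if return_intermediates:
        return out, feat, eq
    return out
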