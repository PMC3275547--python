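"""Local contrast and the contrast improvement ratio (CIR).

Local contrast at a pixel is C = |p − a| / (p + a), where p is the
mean of the 3×3 centre block and a the mean of the surrounding region
of the 7×7 window (the 40 pixels excluding the centre block; a flag
allows the full-49-pixel reading).  The CIR of an enhanced image
relative to the original over an ROI R is

    CIR = Σ_R |C − C̄|² / Σ_R C²,

with C from the original and C̄ from the enhanced image, summed over
the pixels whose 7×7 window lies fully inside R.  Before comparison
both images are linearly stretched to a common [0, 255] scale, so the
ratio measures change in contrast structure, not in absolute level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .enhance import (
    EnhanceParams,
    clahe,
    enhance,
    histogram_equalize,
    linear_stretch,
    multiscale_retinex,
    unsharp_mask,
)
from .morphology import StructuringElement, as_image, make_line_se
from .rmp import RMPConfig

__all__ = [
    "ROISpec",
    "local_contrast",
    "local_contrast_map",
    "cir",
    "cir_from_contrast_maps",
    "compare_methods",
    "METHOD_NAMES",
]

METHOD_NAMES = ("proposed", "he", "lcs", "usm", "msr", "clahe")

#: half-width of the 7x7 contrast window; evaluated pixels keep this margin
_MARGIN = 3


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular region, 0-based (top, left, height, width)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must have positive size")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI indices must be non-negative")

    @classmethod
    def centered(cls, center: tuple[int, int], size: int) -> "ROISpec":
        return cls(center[0] - size // 2, center[1] - size // 2, size, size)

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.top + self.height > shape[0] or self.left + self.width > shape[1]:
            raise ValueError(f"ROI {self} does not fit in image of shape {shape}")
        if self.height < 2 * _MARGIN + 1 or self.width < 2 * _MARGIN + 1:
            raise ValueError("ROI too small for the 7x7 contrast window")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )


def local_contrast_map(image, full_surround: bool = False) -> np.ndarray:
    """C(x, y) at every pixel; valid only where the 7×7 window fits.

    Returns the full-size map (border values are filter artifacts and
    must be excluded by the caller; :func:`cir` does).
    """
    f = as_image(image)
    p = ndimage.uniform_filter(f, size=3, mode="nearest")
    m7 = ndimage.uniform_filter(f, size=7, mode="nearest")
    a = m7 if full_surround else (49.0 * m7 - 9.0 * p) / 40.0
    denom = p + a
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(p - a) / denom
    return np.where(denom != 0, c, 0.0)


def local_contrast(image, x: int, y: int, full_surround: bool = False) -> float:
    """C at pixel (x, y) = |p − a| / (p + a); 0 when p + a = 0."""
    f = as_image(image)
    if not (_MARGIN <= x < f.shape[0] - _MARGIN and _MARGIN <= y < f.shape[1] - _MARGIN):
        raise ValueError(f"7x7 window at ({x}, {y}) is out of bounds")
    center = f[x - 1 : x + 2, y - 1 : y + 2]
    window = f[x - 3 : x + 4, y - 3 : y + 4]
    p = center.mean()
    a = window.mean() if full_surround else (window.sum() - center.sum()) / 40.0
    if p + a == 0:
        return 0.0
    return abs(p - a) / (p + a)


def cir_from_contrast_maps(c_orig, c_enh, roi: ROISpec) -> float:
    """CIR from precomputed contrast maps: Σ|C−C̄|² / ΣC² over the ROI interior."""
    c_orig = as_image(c_orig)
    c_enh = as_image(c_enh)
    if c_orig.shape != c_enh.shape:
        raise ValueError("contrast maps must share a shape")
    roi.validate_for(c_orig.shape)
    inner = (
        slice(roi.top + _MARGIN, roi.top + roi.height - _MARGIN),
        slice(roi.left + _MARGIN, roi.left + roi.width - _MARGIN),
    )
    c = c_orig[inner]
    cb = c_enh[inner]
    denom = float(np.sum(c * c))
    if denom == 0.0:
        raise ValueError(
            "CIR undefined: original image has zero local contrast everywhere "
            f"in ROI {roi}"
        )
    return float(np.sum((c - cb) ** 2)) / denom


def cir(
    original,
    enhanced,
    roi: ROISpec,
    normalize: bool = True,
    full_surround: bool = False,
) -> float:
    """Contrast improvement ratio of `enhanced` over `original` within `roi`.

    With ``normalize`` (default) both images are linearly stretched to
    [0, 255] first, so images on different output scales are compared
    on equal footing.  CIR ≥ 0, and CIR = 0 iff the local contrast is
    unchanged at every evaluated pixel.
    """
    f = as_image(original)
    g = as_image(enhanced)
    if f.shape != g.shape:
        raise ValueError("original and enhanced images must share a shape")
    if normalize:
        f = linear_stretch(f, (0.0, 255.0))
        g = linear_stretch(g, (0.0, 255.0))
    return cir_from_contrast_maps(
        local_contrast_map(f, full_surround),
        local_contrast_map(g, full_surround),
        roi,
    )


def _run_method(name, f, se, config, params):
    if name == "proposed":
        return enhance(f, se, config, params)
    if name == "he":
        return histogram_equalize(f, params.levels)
    if name == "lcs":
        return linear_stretch(f, params.out_range)
    if name == "usm":
        return unsharp_mask(f, params.usm_radius, params.usm_weight)
    if name == "msr":
        return multiscale_retinex(f, params.msr_sigmas, params.msr_weights)
    if name == "clahe":
        return clahe(f, params.clahe_block, params.clahe_clip, params.levels)
    raise ValueError(f"unknown method {name!r}")


def compare_methods(
    original,
    rois: list[ROISpec],
    se: StructuringElement | None = None,
    config: RMPConfig | None = None,
    params: EnhanceParams | None = None,
    return_images: bool = False,
):
    """CIR of the proposed method and five comparison methods per ROI.

    Returns a DataFrame with rows (proposed, he, lcs, usm, msr, clahe)
    and columns R1 … Rk; with ``return_images`` also the dict of
    enhanced images.
    """
    f = as_image(original)
    se = se if se is not None else make_line_se(41)
    config = config or RMPConfig()
    params = params or EnhanceParams()
    for roi in rois:
        roi.validate_for(f.shape)
    images = {name: _run_method(name, f, se, config, params) for name in METHOD_NAMES}
    table = pd.DataFrame(
        {
            f"R{k + 1}": [cir(f, images[name], roi) for name in METHOD_NAMES]
            for k, roi in enumerate(rois)
        },
        index=list(METHOD_NAMES),
    )
    table.index.name = "method"
    if not np.all(np.isfinite(table.values)):
        warnings.warn("non-finite CIR values in comparison table")
    if return_images:
        return table, images
    return table
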