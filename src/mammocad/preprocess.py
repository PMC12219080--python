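"""Mammogram preprocessing: resize, contrast stretch, median denoise.

The full enhancement chain used by the pipeline is
``resize -> contrast_stretch -> median_filter3 -> shearlet_enhance``
(the last stage lives in :mod:`mammocad.shearlet`). All stages are
deterministic and preserve the 8-bit intensity contract of
:class:`~mammocad.io_formats.GrayImage`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .io_formats import GrayImage

__all__ = ["resize_image", "contrast_stretch", "median_filter3"]


def resize_image(img: GrayImage, target: tuple[int, int]) -> GrayImage:
    """Bilinear resize to ``target`` (height, width).

    Uses the half-pixel centre convention: output pixel centre ``d`` samples
    the input at ``(d + 0.5) * scale - 0.5`` with edge clamping, so resizing
    to the same shape is the identity and constants are preserved exactly.
    """
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target dimensions must be >= 1")
    if (th, tw) == (img.height, img.width):
        return GrayImage(img.pixels.copy(), img.max_value)
    rows = (np.arange(th) + 0.5) * (img.height / th) - 0.5
    cols = (np.arange(tw) + 0.5) * (img.width / tw) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        img.astype_float(), [rr, cc], order=1, mode="nearest"
    )
    out = np.clip(np.rint(out), 0, img.max_value).astype(img.pixels.dtype)
    return GrayImage(out, img.max_value)


def contrast_stretch(img: GrayImage) -> GrayImage:
    """Linearly stretch the occupied intensity range onto [0, max_value].

    A constant image has no range to stretch; it maps to all-zero with a
    warning rather than erroring, so degenerate tiles do not abort a batch.
    """
    lo = int(img.pixels.min())
    hi = int(img.pixels.max())
    if hi == lo:
        warnings.warn("contrast_stretch: constant image, output set to zero")
        return GrayImage(np.zeros_like(img.pixels), img.max_value)
    out = np.rint((img.astype_float() - lo) * img.max_value / (hi - lo))
    return GrayImage(out.astype(img.pixels.dtype), img.max_value)


def median_filter3(img: GrayImage) -> GrayImage:
    """3x3 median filter with edge replication at the borders."""
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return GrayImage(out, img.max_value)
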