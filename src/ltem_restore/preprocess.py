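"""First pipeline stage: impulse removal and illumination flattening.

Liquid-cell micrographs carry isolated "very black / very white" outlier
pixels (detector events) and a slowly varying illumination bias. A small
median filter removes the impulses; subtracting per-patch mean intensities
centres every patch at zero so later stages see a bias-free signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import Image, ValidationError

__all__ = ["PreprocessConfig", "median_filter", "illumination_correct", "preprocess"]

_BORDER_MODES = {"reflect": "reflect", "nearest": "nearest"}


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the preprocessing stage.

    median_window: odd side of the median filter window (pixels).
    illum_patch: side of the non-overlapping illumination patches (pixels).
    border_mode: how windows are padded at the image border.
    """

    median_window: int = 3
    illum_patch: int = 64
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValidationError(f"median_window must be odd and >= 1, got {self.median_window}")
        if self.illum_patch < 2:
            raise ValidationError(f"illum_patch must be >= 2, got {self.illum_patch}")
        if self.border_mode not in _BORDER_MODES:
            raise ValidationError(f"border_mode must be one of {sorted(_BORDER_MODES)}")


def median_filter(img: Image, window: int = 3, border_mode: str = "reflect") -> Image:
    """Per-pixel median over a ``window``x``window`` neighbourhood.

    Non-expansive: output values never leave the input range. With the
    default 3x3 window an isolated impulse pixel is removed while 2-pixel
    features survive.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"median window must be odd and >= 1, got {window}")
    if window > min(img.shape):
        raise ValidationError(
            f"median window {window} exceeds image extent {min(img.shape)}"
        )
    if border_mode not in _BORDER_MODES:
        raise ValidationError(f"border_mode must be one of {sorted(_BORDER_MODES)}")
    out = ndimage.median_filter(img.pixels, size=window, mode=_BORDER_MODES[border_mode])
    return img.with_pixels(out)


def illumination_correct(img: Image, patch: int = 64) -> Image:
    """Zero-centre every non-overlapping ``patch``x``patch`` block.

    The image is tiled from the top-left corner; ragged blocks at the
    right/bottom edges are centred as their own smaller blocks so the output
    keeps the input shape. Images smaller than ``patch`` are one single
    block. The output generally contains negative values.
    """
    if patch < 2:
        raise ValidationError(f"illumination patch must be >= 2, got {patch}")
    arr = img.pixels.copy()
    h, w = arr.shape
    for top in range(0, h, patch):
        for left in range(0, w, patch):
            block = arr[top : top + patch, left : left + patch]
            block -= block.mean()
    return img.with_pixels(arr)


def preprocess(img: Image, cfg: PreprocessConfig = PreprocessConfig()) -> tuple[Image, Image]:
    """Run the full preprocessing stage.

    Returns ``(i_nd, i_centered)``: the median-filtered image (reused later
    as the sharp/noisy input to deblurring) and its illumination-corrected,
    zero-centred version (the denoiser input).
    """
    i_nd = median_filter(img, cfg.median_window, cfg.border_mode)
    i_centered = illumination_correct(i_nd, cfg.illum_patch)
    return i_nd, i_centered
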