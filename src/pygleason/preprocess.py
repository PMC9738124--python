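"""Slide-level histogram equalization, patch-level edge enhancement, tissue mask."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import color

from .synthetic import SlideImage

__all__ = [
    "PreprocessConfig",
    "histogram_equalize",
    "enhance_edges",
    "tissue_mask",
]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    heq_mode
        ``"luminance"`` equalizes the Y channel of YCbCr and keeps chroma
        (avoids hue distortion); ``"per_channel"`` equalizes R, G, B
        independently.
    ee_amount
        Unsharp-mask gain; 0 disables edge enhancement (identity).
    ee_radius
        Gaussian blur radius (sigma) of the unsharp mask, in pixels.
    tissue_threshold
        A pixel is background iff all three channels are >= this value.
    apply_ee_at_test
        Whether edge enhancement is also applied to inference patches.
    """

    heq_mode: str = "luminance"
    ee_amount: float = 1.0
    ee_radius: float = 1.5
    tissue_threshold: int = 240
    apply_ee_at_test: bool = True

    def validate(self) -> None:
        if self.heq_mode not in ("luminance", "per_channel"):
            raise ValueError(f"unknown heq_mode {self.heq_mode!r}")
        if self.ee_radius <= 0:
            raise ValueError("ee_radius must be > 0")
        if self.ee_amount < 0:
            raise ValueError("ee_amount must be >= 0")
        if not (0 <= self.tissue_threshold <= 256):
            raise ValueError("tissue_threshold must lie in [0, 256]")


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    """Classic CDF-based histogram equalization of one uint8 channel.

    The mapping is the (scaled) empirical CDF, hence monotone non-decreasing
    by construction.
    """
    hist = np.bincount(channel.ravel(), minlength=256).astype(np.float64)
    cdf = hist.cumsum()
    nonzero = cdf > 0
    if not nonzero.any():
        return channel
    cdf_min = cdf[nonzero][0]
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # constant image
        return channel
    lut = np.rint((cdf - cdf_min) / denom * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]


def histogram_equalize(slide: SlideImage, cfg: PreprocessConfig | None = None) -> SlideImage:
    """Equalize slide intensities; the label map passes through untouched."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    rgb = np.asarray(slide.rgb)
    if rgb.size == 0:
        raise ValueError("empty image")

    if cfg.heq_mode == "per_channel":
        out = np.stack([_equalize_channel(rgb[..., c]) for c in range(3)], axis=-1)
    else:
        ycbcr = color.rgb2ycbcr(rgb)
        y = np.clip(np.rint(ycbcr[..., 0]), 0, 255).astype(np.uint8)
        y_eq = _equalize_channel(y).astype(np.float64)
        # rgb2ycbcr puts luma in [16, 235]; rescale the equalized channel back
        ycbcr[..., 0] = 16.0 + y_eq * (235.0 - 16.0) / 255.0
        out = np.clip(np.rint(color.ycbcr2rgb(ycbcr) * 255.0), 0, 255).astype(np.uint8)

    return SlideImage(rgb=out, label_map=slide.label_map)


def enhance_edges(patch: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Unsharp masking: ``out = patch + amount * (patch - blur(patch))``.

    With ``ee_amount == 0`` the input is returned unchanged (same dtype).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    patch = np.asarray(patch)
    if cfg.ee_amount == 0:
        return patch.copy()
    as_float = patch.astype(np.float64)
    sigma = (cfg.ee_radius, cfg.ee_radius, 0) if patch.ndim == 3 else cfg.ee_radius
    blurred = gaussian_filter(as_float, sigma=sigma)
    sharp = as_float + cfg.ee_amount * (as_float - blurred)
    return np.clip(np.rint(sharp), 0, 255).astype(patch.dtype)


def tissue_mask(slide: SlideImage, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Boolean raster: True where the pixel is tissue.

    If the slide carries a ground-truth label map, tissue is ``label != 0``;
    otherwise a pixel is background iff all channels >= ``tissue_threshold``.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if slide.label_map is not None:
        return np.asarray(slide.label_map) != 0
    rgb = np.asarray(slide.rgb)
    background = (rgb >= cfg.tissue_threshold).all(axis=-1)
    return ~background
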