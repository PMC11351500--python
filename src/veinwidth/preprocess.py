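"""Preprocessing chain for near-infrared forearm images.

The chain runs crop/background removal, percentile contrast stretching,
median denoising, an optional first enhancement stage, and CLAHE, in that
fixed order.  NIR vein images show hemoglobin-rich vessels as dark tubes on
brighter tissue, typically blurred, noisy and low-contrast; each stage
addresses one of those defects.  A :class:`PreprocessReport` records what was
actually run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu

from .config import PipelineConfig
from .errors import ConfigurationError, ValidationError
from .io import as_gray_image

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "crop_and_remove_background",
    "contrast_stretch",
    "median_denoise",
    "enhance_stage1",
    "clahe_enhance",
    "preprocess_image",
]


@dataclass
class PreprocessReport:
    """Provenance of one preprocessing run."""

    crop_box: Optional[Tuple[int, int, int, int]] = None
    stretch_range: Optional[Tuple[float, float]] = None
    stages: List[str] = field(default_factory=list)


def crop_and_remove_background(img, box=None, margin: int = 3, report: Optional[PreprocessReport] = None):
    """Crop to the arm region and flatten everything outside it.

    With an explicit ``box`` (``(r0, r1, c0, c1)``, half-open) the sub-image
    is returned as-is.  With ``box=None`` the arm is found as the largest
    connected component above an Otsu threshold of the image (the arm is the
    bright region under NIR illumination); the crop is that component's
    bounding box padded by ``margin``, and pixels outside the component are
    set to the median intensity of the component border so that non-arm
    clutter cannot seed later stages.
    """
    img = as_gray_image(img)
    h, w = img.shape
    if box is not None:
        r0, r1, c0, c1 = (int(v) for v in box)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValidationError(f"crop box {box} outside image of shape {img.shape}")
        out = img[r0:r1, c0:c1].copy()
        if report is not None:
            report.crop_box = (r0, r1, c0, c1)
            report.stages.append("crop")
        return out

    if img.min() == img.max():
        raise ValidationError("cannot locate arm region in a constant image")
    t = threshold_otsu(img)
    fg = img > t
    # close over dark vessels crossing the arm so they stay inside the
    # component instead of splitting it (vessels are at most ~10 px wide here)
    fg = ndi.binary_closing(fg, structure=np.ones((3, 3), bool), iterations=5,
                            border_value=1)
    labels, nlab = ndi.label(fg)
    if nlab == 0:
        raise ValidationError("no foreground component found for automatic crop")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    # dark vessels are holes inside the bright arm region; keep them
    comp = ndi.binary_fill_holes(comp)
    rows = np.any(comp, axis=1).nonzero()[0]
    cols = np.any(comp, axis=0).nonzero()[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(h, rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(w, cols[-1] + 1 + margin)

    border = comp ^ ndi.binary_erosion(comp)
    bg_value = int(np.median(img[border])) if border.any() else int(np.median(img[comp]))
    out = img.copy()
    out[~comp] = bg_value
    out = out[r0:r1, c0:c1]
    if report is not None:
        report.crop_box = (r0, r1, c0, c1)
        report.stages.append("crop")
    return out


def contrast_stretch(img, low_pct: float = 1.0, high_pct: float = 99.0,
                     report: Optional[PreprocessReport] = None):
    """Linearly map the [low_pct, high_pct] intensity percentiles to [0, 255].

    Percentile endpoints (rather than min/max) keep isolated hot pixels from
    collapsing the output range.  A constant image is returned unchanged with
    a warning.
    """
    img = as_gray_image(img)
    if not (0 <= low_pct < high_pct <= 100):
        raise ValidationError("percentiles must satisfy 0 <= low < high <= 100")
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        logger.warning("contrast_stretch: degenerate intensity range, image unchanged")
        if report is not None:
            report.stretch_range = (float(lo), float(hi))
            report.stages.append("stretch")
        return img.copy()
    out = (img.astype(np.float64) - lo) * (255.0 / (hi - lo))
    out = np.clip(out, 0, 255)
    if report is not None:
        report.stretch_range = (float(lo), float(hi))
        report.stages.append("stretch")
    return as_gray_image(out)


def median_denoise(img, window: int = 3, report: Optional[PreprocessReport] = None):
    """Median filter with an odd square window; borders replicate the edge."""
    img = as_gray_image(img)
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"median window must be odd and >= 3, got {window}")
    out = ndi.median_filter(img, size=window, mode="nearest")
    if report is not None:
        report.stages.append("median")
    return out


def enhance_stage1(img, mode: str = "unsharp", amount: float = 1.0,
                   sigma: float = 2.0, model=None,
                   report: Optional[PreprocessReport] = None):
    """First (local-detail) enhancement stage.

    ``off`` is the identity.  ``unsharp`` adds back the high-pass residual,
    ``img + amount * (img - G_sigma * img)``, the package's stand-in for a
    learned residual enhancer.  ``autoencoder`` calls a user-supplied model
    object (``model(img) -> img``); none is bundled.
    """
    img = as_gray_image(img)
    if mode == "off":
        out = img.copy()
    elif mode == "unsharp":
        blurred = ndi.gaussian_filter(img.astype(np.float64), sigma=sigma, mode="nearest")
        out = as_gray_image(np.clip(img + amount * (img - blurred), 0, 255))
    elif mode == "autoencoder":
        if model is None:
            raise ConfigurationError("autoencoder enhancement requires a supplied model")
        out = as_gray_image(model(img))
    else:
        raise ValidationError(f"unknown enhancement mode {mode!r}")
    if report is not None:
        report.stages.append("enhance_stage1")
    return out


def clahe_enhance(img, clip_limit: float = 0.01, tiles: Tuple[int, int] = (8, 8),
                  report: Optional[PreprocessReport] = None):
    """Contrast-limited adaptive histogram equalization.

    The image is split into a ``tiles`` grid; each tile's histogram is
    clipped at ``clip_limit`` (a fraction of the tile pixel count, so the
    setting is resolution independent), the excess is redistributed, and the
    per-tile mappings are blended bilinearly to avoid block seams.  Tiles
    larger than the image fall back to a single global tile.
    """
    img = as_gray_image(img)
    if clip_limit <= 0:
        raise ValidationError("clip limit must be positive")
    tr, tc = int(tiles[0]), int(tiles[1])
    if tr < 1 or tc < 1:
        raise ValidationError("tile grid must be at least 1x1")
    if img.min() == img.max():
        if report is not None:
            report.stages.append("clahe")
        return img.copy()
    h, w = img.shape
    kernel = (max(1, h // tr), max(1, w // tc))
    if kernel[0] > h or kernel[1] > w:
        logger.warning("clahe_enhance: tile larger than image, using one global tile")
        kernel = (h, w)
    out = equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit, nbins=256)
    if report is not None:
        report.stages.append("clahe")
    return as_gray_image(out * 255.0)


def preprocess_image(img, cfg: PipelineConfig):
    """Run the full fixed-order chain; returns (image, report)."""
    report = PreprocessReport()
    out = crop_and_remove_background(img, box=cfg.crop_box, margin=cfg.crop_margin, report=report)
    out = contrast_stretch(out, cfg.stretch_low_pct, cfg.stretch_high_pct, report=report)
    out = median_denoise(out, cfg.median_window, report=report)
    if cfg.enhance_mode != "off":
        out = enhance_stage1(out, mode=cfg.enhance_mode, amount=cfg.unsharp_amount,
                             sigma=cfg.unsharp_sigma, model=cfg.enhance_model, report=report)
    out = clahe_enhance(out, cfg.clahe_clip, cfg.clahe_tiles, report=report)
    return out, report
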