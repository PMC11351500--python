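"""Canny edge detection, built from its five classical steps.

Gaussian denoising, Sobel gradients (magnitude ``sqrt(gx^2+gy^2)`` and
quadrant-aware direction), non-maximum suppression along the quantized
gradient direction, double thresholding into strong/weak edges, and
hysteresis tracking that keeps only weak edges 8-connected to a strong one.
The x axis is the image column axis and y the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .io import as_gray_image

__all__ = [
    "GradientField",
    "EdgeMap",
    "gaussian_smooth",
    "sobel_gradients",
    "non_maximum_suppress",
    "hysteresis_threshold",
    "canny",
    "mask_boundary_edges",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T


@dataclass
class GradientField:
    """Sobel gradients: components, magnitude, and direction in (-pi, pi]."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class EdgeMap:
    """Final edge pixels (boolean grid) and their coordinates."""

    pixels: np.ndarray
    edge_points: List[Tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "EdgeMap":
        pts = [(int(r), int(c)) for r, c in zip(*np.nonzero(pixels))]
        return cls(pixels=np.asarray(pixels, dtype=bool), edge_points=pts)


def gaussian_kernel(eta: float) -> np.ndarray:
    """2-D Gaussian kernel truncated at +/- ceil(3*eta), renormalized to 1."""
    if eta <= 0:
        raise ValidationError("eta must be positive")
    radius = int(np.ceil(3 * eta))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2 * eta ** 2)) / (2 * np.pi * eta ** 2)
    return k / k.sum()


def gaussian_smooth(img, eta: float = 1.0) -> np.ndarray:
    """Convolve with the truncated, renormalized Gaussian (edge replication)."""
    img = as_gray_image(img).astype(np.float64)
    return ndi.convolve(img, gaussian_kernel(eta), mode="nearest")


def sobel_gradients(img) -> GradientField:
    """3x3 Sobel gradients of a (smoothed, real-valued) image."""
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {a.shape}")
    # correlation, not convolution: the kernels are written in the usual
    # sliding-window orientation (positive gx for intensity increasing with x)
    gx = ndi.correlate(a, SOBEL_X, mode="nearest")
    gy = ndi.correlate(a, SOBEL_Y, mode="nearest")
    mag = np.sqrt(gx ** 2 + gy ** 2)
    direction = np.arctan2(gy, gx)
    return GradientField(gx=gx, gy=gy, magnitude=mag, direction=direction)


def non_maximum_suppress(grad: GradientField) -> np.ndarray:
    """Keep pixels whose magnitude is >= both neighbors along the gradient
    direction quantized to 0/45/90/135 degrees; zero the rest."""
    mag = grad.magnitude
    h, w = mag.shape
    # sector 0: horizontal gradient (compare left/right), 1: 45, 2: vertical, 3: 135
    angle = np.mod(np.degrees(grad.direction), 180.0)
    sector = np.zeros_like(angle, dtype=np.int8)
    sector[(angle >= 22.5) & (angle < 67.5)] = 1
    sector[(angle >= 67.5) & (angle < 112.5)] = 2
    sector[(angle >= 112.5) & (angle < 157.5)] = 3

    padded = np.pad(mag, 1, mode="constant")

    def shifted(dr, dc):
        return padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]

    # neighbor offsets along the gradient direction per sector; y (rows) grows
    # downward, so a +45-degree direction (gx>0, gy>0) points down-right
    neighbor_pairs = {
        0: ((0, 1), (0, -1)),
        1: ((1, 1), (-1, -1)),
        2: ((1, 0), (-1, 0)),
        3: ((1, -1), (-1, 1)),
    }
    keep = np.zeros_like(mag, dtype=bool)
    for s, ((dr1, dc1), (dr2, dc2)) in neighbor_pairs.items():
        sel = sector == s
        keep |= sel & (mag >= shifted(dr1, dc1)) & (mag >= shifted(dr2, dc2))
    out = np.where(keep & (mag > 0), mag, 0.0)
    return out


def hysteresis_threshold(nms: np.ndarray, low: float, high: float) -> EdgeMap:
    """Double threshold + edge tracking.

    Strong edges have magnitude > high; weak edges lie in (low, high].  The
    final edge set is the strong pixels plus every weak pixel connected to a
    strong one through an 8-connected strong/weak chain.
    """
    if not (0 <= low < high):
        raise ValidationError("thresholds must satisfy 0 <= low < high")
    nms = np.asarray(nms, dtype=np.float64)
    strong = nms > high
    candidate = nms > low  # strong | weak
    labels, _ = ndi.label(candidate, structure=np.ones((3, 3), bool))
    keep_labels = np.unique(labels[strong])
    keep_labels = keep_labels[keep_labels > 0]
    edges = np.isin(labels, keep_labels)
    return EdgeMap.from_pixels(edges)


def canny(img, eta: float = 1.0, low: float = 0.1, high: float = 0.2,
          relative: bool = True) -> EdgeMap:
    """Full Canny detector.

    With ``relative=True`` (default) the thresholds are fractions of the
    maximum gradient magnitude after suppression; otherwise they are absolute
    magnitudes.
    """
    smoothed = gaussian_smooth(img, eta)
    grad = sobel_gradients(smoothed)
    nms = non_maximum_suppress(grad)
    # float residue of the renormalized kernel on flat images is not signal
    nms[nms < 1e-6] = 0.0
    if relative:
        peak = nms.max()
        if peak == 0:
            return EdgeMap.from_pixels(np.zeros_like(nms, dtype=bool))
        low, high = low * peak, high * peak
    return hysteresis_threshold(nms, low, high)


def mask_boundary_edges(mask, offset: str = "outside") -> EdgeMap:
    """Edge map from a segmentation mask boundary.

    ``outside``: the first background pixels 4-adjacent to the mask;
    ``inside``: the outermost mask pixels.  The outside convention pairs with
    the tangent-circle diameter rule d = 2r - 1 (edges sit one pixel beyond
    the lumen).
    """
    mask = np.asarray(mask, dtype=bool)
    cross = ndi.generate_binary_structure(2, 1)
    if offset == "outside":
        edges = ndi.binary_dilation(mask, structure=cross) & ~mask
    elif offset == "inside":
        edges = mask & ~ndi.binary_erosion(mask, structure=cross, border_value=1)
    else:
        raise ValidationError(f"unknown edge offset {offset!r}")
    return EdgeMap.from_pixels(edges)
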