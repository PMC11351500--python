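"""RETC: radius estimation of the tangent circle.

At every skeleton (centerline) point a circle is grown in discrete radius
steps until it first touches a vessel-edge pixel; that radius r gives the
local diameter d = 2r - 1 (the edge sits one pixel outside the lumen, so the
lumen spans the pixels strictly between opposing first contacts), and the
segment width D is the mean of the per-point diameters.  Distances are true
Euclidean distances between pixel centers.

Skeleton points whose circle never meets an edge within ``r_max`` (e.g. a
spur pointing into an edge gap) are excluded from the mean and counted, not
fatal.  :func:`retc_oracle` computes the same profile by an exhaustive
nearest-edge scan with no radius loop and must agree exactly for r_step=1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .edges import EdgeMap
from .errors import ValidationError
from .skeleton import SkeletonMap

logger = logging.getLogger(__name__)

__all__ = [
    "WidthEntry",
    "WidthProfile",
    "tangent_radius",
    "diameter_from_radius",
    "retc_width_profile",
    "retc_oracle",
]


@dataclass(frozen=True)
class WidthEntry:
    """One skeleton point's tangent-circle result."""

    index: int
    row: int
    col: int
    radius: float
    diameter: float


@dataclass
class WidthProfile:
    """Per-point radii/diameters plus the segment mean width D."""

    entries: List[WidthEntry] = field(default_factory=list)
    excluded: int = 0  # skeleton points with no edge within r_max

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.radius < 1:
                raise ValidationError(f"radius must be >= 1, got {e.radius}")
            if abs(e.diameter - (2 * e.radius - 1)) > 1e-9:
                raise ValidationError("diameter must equal 2*radius - 1")

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def mean_width(self) -> float:
        """D = (1/n) * sum(d_i) over the included skeleton points."""
        if not self.entries:
            raise ValidationError("width profile has no entries")
        return float(np.mean([e.diameter for e in self.entries]))

    @property
    def diameters(self) -> np.ndarray:
        return np.array([e.diameter for e in self.entries], dtype=np.float64)


def diameter_from_radius(r: float) -> float:
    """Pixel diameter of the tangent circle: d = 2r - 1."""
    if r < 1:
        raise ValidationError(f"radius must be >= 1, got {r}")
    return 2 * r - 1


def _edge_coords(edges: EdgeMap) -> np.ndarray:
    coords = np.argwhere(np.asarray(edges.pixels, dtype=bool))
    if coords.size == 0:
        raise ValidationError("edge map is empty")
    return coords.astype(np.float64)


def tangent_radius(center: Tuple[int, int], edges: EdgeMap,
                   r_max: Optional[int] = None, r_step: int = 1,
                   _coords: Optional[np.ndarray] = None) -> Optional[float]:
    """Grow the circle at ``center`` until it first touches an edge pixel.

    Returns the smallest radius in {r_step, 2*r_step, ...} at which some edge
    pixel lies within Euclidean distance <= r of the center, or None when no
    edge is reached within ``r_max`` (capped at the image diagonal).
    """
    coords = _edge_coords(edges) if _coords is None else _coords
    if r_step < 1:
        raise ValidationError("r_step must be >= 1")
    if r_max is None:
        r_max = int(min(edges.pixels.shape))
    d = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    r = r_step
    while r <= r_max:
        if np.any(d <= r):
            return float(r)
        r += r_step
    return None


def retc_width_profile(skel: SkeletonMap, edges: EdgeMap,
                       r_max: Optional[int] = None, r_step: int = 1) -> WidthProfile:
    """Apply the tangent-circle search at every skeleton point.

    The outer loop walks the skeleton in traversal order; unreachable points
    are excluded from the mean (with a warning) rather than aborting.
    """
    if np.asarray(skel.pixels).shape != np.asarray(edges.pixels).shape:
        raise ValidationError("skeleton and edge map must share image shape")
    points = skel.points or [(int(r), int(c)) for r, c in zip(*np.nonzero(skel.pixels))]
    if not points:
        raise ValidationError("skeleton is empty")
    coords = _edge_coords(edges)
    entries: List[WidthEntry] = []
    excluded = 0
    for i, (r0, c0) in enumerate(points):
        r = tangent_radius((r0, c0), edges, r_max=r_max, r_step=r_step, _coords=coords)
        if r is None:
            excluded += 1
            continue
        entries.append(WidthEntry(index=i, row=r0, col=c0, radius=r,
                                  diameter=diameter_from_radius(r)))
    if excluded:
        logger.warning("RETC: %d skeleton point(s) had no edge within r_max", excluded)
    if not entries:
        raise ValidationError("every skeleton point was excluded: no edges in reach")
    return WidthProfile(entries=entries, excluded=excluded)


def retc_oracle(skel: SkeletonMap, edges: EdgeMap,
                r_max: Optional[int] = None, r_step: int = 1) -> WidthProfile:
    """Radius by direct nearest-edge distance: r = ceil(min dist / r_step) * r_step.

    Independent of the radius-growth loop; used to cross-check
    :func:`retc_width_profile`, with which it must agree exactly.
    """
    if np.asarray(skel.pixels).shape != np.asarray(edges.pixels).shape:
        raise ValidationError("skeleton and edge map must share image shape")
    points = skel.points or [(int(r), int(c)) for r, c in zip(*np.nonzero(skel.pixels))]
    if not points:
        raise ValidationError("skeleton is empty")
    coords = _edge_coords(edges)
    if r_max is None:
        r_max = int(min(edges.pixels.shape))
    entries: List[WidthEntry] = []
    excluded = 0
    for i, (r0, c0) in enumerate(points):
        dmin = np.hypot(coords[:, 0] - r0, coords[:, 1] - c0).min()
        r = r_step * math.ceil(dmin / r_step)
        r = max(r, r_step)  # a skeleton point on an edge pixel still needs r >= 1 step
        if r > r_max:
            excluded += 1
            continue
        entries.append(WidthEntry(index=i, row=r0, col=c0, radius=float(r),
                                  diameter=diameter_from_radius(float(r))))
    if not entries:
        raise ValidationError("every skeleton point was excluded: no edges in reach")
    return WidthProfile(entries=entries, excluded=excluded)
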