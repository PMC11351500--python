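"""Manual-reference ruler procedure and evaluation statistics.

The reference width of a vessel is measured by placing a ruler through a
chosen point and reading the foreground chord length, rotating the ruler in
20-degree steps from 0 to 160 degrees (nine readings) and taking the
minimum; the shortest chord crosses the vessel perpendicular to its axis.
Per-image errors against such references are summarized by their mean and
population variance, and a per-image relative accuracy 1 - |est - ref| / ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "RulerMeasurement",
    "EvalReport",
    "ruler_reading",
    "reference_width",
    "error_stats",
    "accuracy",
    "DEFAULT_ANGLES",
]

DEFAULT_ANGLES: Tuple[float, ...] = tuple(float(a) for a in range(0, 161, 20))

_STEP = 0.25  # sub-pixel sampling step along the ruler, in px


@dataclass
class RulerMeasurement:
    """Nine directional chord readings at one anchor and their minimum."""

    anchor: Tuple[int, int]
    angles: List[float]
    readings: List[float]
    reference_width: float


@dataclass
class EvalReport:
    """Per-image absolute errors e_i plus mean, population variance, accuracy."""

    errors: List[float]
    mean_error: float
    variance_error: float
    accuracies: List[float]
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = len(self.errors)


def _direction(angle_deg: float) -> Tuple[float, float]:
    """(drow, dcol) unit vector; angles counterclockwise from the +col axis."""
    a = np.deg2rad(angle_deg)
    return (-np.sin(a), np.cos(a))


def ruler_reading(mask, anchor: Tuple[int, int], angle_deg: float) -> float:
    """Chord length (px) of the foreground run through ``anchor`` along
    ``angle_deg``, sampled every 0.25 px with nearest-pixel lookup.

    The reading counts contiguous foreground samples times the step, which
    for an axis-aligned band equals its pixel width.
    """
    mask = np.asarray(mask, dtype=bool)
    r0, c0 = anchor
    h, w = mask.shape
    if not (0 <= r0 < h and 0 <= c0 < w) or not mask[int(r0), int(c0)]:
        raise ValidationError(f"anchor {anchor} is not a foreground pixel")
    dr, dc = _direction(angle_deg)

    def is_fg(t: float) -> bool:
        # nearest-pixel lookup; floor(x + 0.5) avoids banker's rounding
        r = int(np.floor(r0 + t * dr + 0.5))
        c = int(np.floor(c0 + t * dc + 0.5))
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    max_steps = int(np.ceil(np.hypot(h, w) / _STEP)) + 1
    count = 1  # the anchor sample (t = 0)
    for sign in (1.0, -1.0):
        k = 1
        while k <= max_steps and is_fg(sign * k * _STEP):
            count += 1
            k += 1
    return count * _STEP


def reference_width(mask, anchor: Tuple[int, int],
                    angles: Sequence[float] = DEFAULT_ANGLES) -> RulerMeasurement:
    """Nine-angle ruler measurement; the reference width is the minimum reading."""
    readings = [ruler_reading(mask, anchor, a) for a in angles]
    return RulerMeasurement(anchor=tuple(anchor), angles=list(angles),
                            readings=readings, reference_width=min(readings))


def error_stats(estimates: Sequence[float], references: Sequence[float]) -> EvalReport:
    """Absolute errors e_i = |est_i - ref_i|, their mean and population
    variance (divisor n), plus per-image accuracies."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.size == 0 or est.shape != ref.shape:
        raise ValidationError("estimates and references must be equal-length and non-empty")
    e = np.abs(est - ref)
    mu = float(e.mean())
    var = float(np.mean((e - mu) ** 2))
    accs = [accuracy(w, r) for w, r in zip(est, ref)]
    return EvalReport(errors=e.tolist(), mean_error=mu, variance_error=var,
                      accuracies=accs, n=int(e.size))


def accuracy(estimate: float, reference: float) -> float:
    """Relative accuracy 1 - |estimate - reference| / reference, 2 decimals."""
    if reference <= 0:
        raise ValidationError("reference width must be positive")
    return round(1.0 - abs(estimate - reference) / reference, 2)
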