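"""Zhang-Suen two-subiteration thinning.

The classic parallel thinning scheme reduces a binary vessel mask to a
one-pixel-wide skeleton while preserving connectivity.  Neighbors of a pixel
P1 are labeled P2..P9 clockwise starting from the north neighbor:

        P9 P2 P3
        P8 P1 P4
        P7 P6 P5

A pixel is deleted in subiteration 1 when (a) its neighbor count B is in
[2, 6], (b) the cyclic 0->1 transition count A around P2..P9 equals 1, and
(c) P2*P4*P6 = 0 and P4*P6*P8 = 0; subiteration 2 swaps the directional
products for P2*P4*P8 = 0 and P2*P6*P8 = 0.  Iteration stops when a full
pass deletes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "SkeletonMap",
    "neighbor_count",
    "transition_count",
    "zhang_suen_thin",
    "skeleton_points",
    "prune_spurs",
]

# offsets of P2..P9 relative to P1, clockwise from north, in (row, col)
NEIGHBOR_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass
class SkeletonMap:
    """One-pixel-wide skeleton: boolean grid plus traversal-ordered points."""

    pixels: np.ndarray
    points: List[Tuple[int, int]] = field(default_factory=list)


def neighbor_count(neighbors) -> int:
    """B(P1): number of foreground pixels among P2..P9."""
    nb = [int(bool(v)) for v in neighbors]
    if len(nb) != 8:
        raise ValidationError("a 3x3 neighborhood has exactly 8 neighbors")
    return sum(nb)


def transition_count(neighbors) -> int:
    """A(P1): 0->1 transitions in the cyclic sequence P2,P3,...,P9,P2."""
    nb = [int(bool(v)) for v in neighbors]
    if len(nb) != 8:
        raise ValidationError("a 3x3 neighborhood has exactly 8 neighbors")
    return sum(1 for a, b in zip(nb, nb[1:] + nb[:1]) if a == 0 and b == 1)


def _neighbor_planes(a: np.ndarray) -> List[np.ndarray]:
    """P2..P9 of every pixel as eight shifted copies (zero-padded borders)."""
    p = np.pad(a, 1, mode="constant")
    h, w = a.shape
    return [p[1 + dr:1 + dr + h, 1 + dc:1 + dc + w] for dr, dc in NEIGHBOR_OFFSETS]


def _thin_pass(a: np.ndarray, second: bool) -> np.ndarray:
    """One subiteration: returns the deletion mask."""
    nb = _neighbor_planes(a)
    p2, p3, p4, p5, p6, p7, p8, p9 = nb
    b = sum(n.astype(np.int8) for n in nb)
    seq = nb + [nb[0]]
    trans = sum(((seq[i] == 0) & (seq[i + 1] == 1)) for i in range(8))
    if not second:
        cond3 = (p2 * p4 * p6) == 0
        cond4 = (p4 * p6 * p8) == 0
    else:
        cond3 = (p2 * p4 * p8) == 0
        cond4 = (p2 * p6 * p8) == 0
    return (a == 1) & (b >= 2) & (b <= 6) & (trans == 1) & cond3 & cond4


def zhang_suen_thin(mask, max_iters: int = 100) -> SkeletonMap:
    """Thin a binary mask to its Zhang-Suen skeleton.

    Runs (mark subiteration 1, delete; mark subiteration 2, delete) until a
    full iteration deletes nothing or ``max_iters`` is reached.  The returned
    :class:`SkeletonMap` carries points in endpoint-to-endpoint traversal
    order (depth-first through branches).
    """
    a = np.asarray(mask).astype(np.uint8)
    if a.ndim != 2:
        raise ValidationError(f"expected a 2-D mask, got shape {a.shape}")
    if not a.any():
        raise ValidationError("cannot thin an empty mask")
    for _ in range(max_iters):
        changed = False
        for second in (False, True):
            deletion = _thin_pass(a, second)
            if deletion.any():
                a[deletion] = 0
                changed = True
        if not changed:
            break
    skel = SkeletonMap(pixels=a.astype(bool))
    skel.points = skeleton_points(skel)
    return skel


def skeleton_points(skel: SkeletonMap) -> List[Tuple[int, int]]:
    """Traversal-ordered skeleton coordinates, every pixel exactly once.

    Each 8-connected component is walked depth-first starting from an
    endpoint (a pixel with a single skeleton neighbor) when one exists, so a
    simple curve lists its pixels end to end.
    """
    pixels = np.asarray(skel.pixels, dtype=bool)
    if not pixels.any():
        raise ValidationError("empty skeleton has no points")
    coords = set(zip(*np.nonzero(pixels)))
    coords = {(int(r), int(c)) for r, c in coords}

    def neighbors(p):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in NEIGHBOR_OFFSETS
                if (r + dr, c + dc) in coords]

    visited = set()
    order: List[Tuple[int, int]] = []
    # endpoints first so open curves traverse end-to-end
    starts = sorted(coords, key=lambda p: (len(neighbors(p)) != 1, p))
    for start in starts:
        if start in visited:
            continue
        stack = [start]
        while stack:
            p = stack.pop()
            if p in visited:
                continue
            visited.add(p)
            order.append(p)
            for q in sorted(neighbors(p), reverse=True):
                if q not in visited:
                    stack.append(q)
    return order


def prune_spurs(skel: SkeletonMap, min_length: int) -> SkeletonMap:
    """Remove side branches shorter than ``min_length``.

    Each branch is walked from its endpoint toward the first junction (pixel
    with three or more skeleton neighbors); branches that reach the junction
    in fewer than ``min_length`` pixels are deleted whole.  Branches ending
    at another endpoint (the main curve) are kept.  ``min_length <= 0``
    disables pruning.
    """
    pixels = np.asarray(skel.pixels, dtype=bool).copy()
    if min_length <= 0:
        return SkeletonMap(pixels=pixels, points=list(skel.points))
    coords = {(int(r), int(c)) for r, c in zip(*np.nonzero(pixels))}

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in NEIGHBOR_OFFSETS
                if (p[0] + dr, p[1] + dc) in coords]

    for start in [p for p in coords if len(neighbors(p)) == 1]:
        if start not in coords:
            continue  # consumed by an earlier prune
        path = [start]
        prev = None
        cur = start
        while True:
            nxt = [q for q in neighbors(cur) if q != prev]
            if len(nxt) != 1:
                break  # junction or dead end
            prev, cur = cur, nxt[0]
            if len(neighbors(cur)) > 2:
                break  # reached a junction: path is a side branch
            path.append(cur)
        if len(neighbors(cur)) > 2 and len(path) < min_length:
            for p in path:
                coords.discard(p)
                pixels[p] = False
    if not pixels.any():
        return SkeletonMap(pixels=np.asarray(skel.pixels, dtype=bool).copy(),
                           points=list(skel.points))
    # pruning can leave a one-pixel nub where the branch met the curve;
    # a re-thin restores the canonical skeleton
    return zhang_suen_thin(pixels)
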