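"""Raster and table I/O.

Images are 2-D ``uint8`` numpy arrays in (row, col) order, row 0 at the top —
the package's working currency.  PNG, TIFF and PGM are supported through
Pillow; multi-channel inputs are collapsed by channel averaging and deeper
bit depths are rescaled to 0–255.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError, ValidationError

__all__ = [
    "as_gray_image",
    "read_gray_image",
    "write_gray_image",
    "mask_to_image",
    "image_to_mask",
    "write_width_table",
]


def as_gray_image(arr) -> np.ndarray:
    """Validate and convert *arr* to a uint8 grayscale image.

    Accepts integer arrays in 0–255 or real arrays in [0, 1] (scaled up).
    Raises :class:`ValidationError` on wrong dimensionality or range.
    """
    a = np.asarray(arr)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValidationError(f"expected a 2-D image, got shape {a.shape}")
    if np.issubdtype(a.dtype, np.floating):
        if not np.isfinite(a).all():
            raise ValidationError("image contains non-finite values")
        if a.min() < 0 or a.max() > 255:
            raise ValidationError("float image values outside [0, 255]")
        if a.max() <= 1.0:
            a = a * 255.0
        # round half up, matching the package-wide integer conversion rule
        return np.floor(a + 0.5).astype(np.uint8)
    if a.min() < 0 or a.max() > 255:
        raise ValidationError("integer image values outside [0, 255]")
    return a.astype(np.uint8)


def read_gray_image(path) -> np.ndarray:
    """Read a PNG/TIFF/PGM raster as a uint8 grayscale image.

    Multi-channel images are converted by averaging the channels; bit depths
    above 8 are rescaled into 0–255.
    """
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise InputError(f"cannot read image: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises several unrelated types
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 3:  # channel-average luminance; alpha ignored
        arr = arr[..., :3].astype(np.float64).mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # >8-bit raster
        arr = arr * (255.0 / arr.max())
    return as_gray_image(arr)


def write_gray_image(img, path) -> None:
    """Write a grayscale image losslessly (format chosen by extension)."""
    img = as_gray_image(img)
    path = Path(path)
    if not path.parent.is_dir():
        raise InputError(f"output directory does not exist: {path.parent}")
    try:
        Image.fromarray(img, mode="L").save(path)
    except OSError as exc:
        raise InputError(f"cannot write image {path}: {exc}") from exc


def mask_to_image(mask) -> np.ndarray:
    """Encode a boolean mask as a 0/255 grayscale image."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"expected a 2-D mask, got shape {mask.shape}")
    return np.where(mask.astype(bool), 255, 0).astype(np.uint8)


def image_to_mask(img) -> np.ndarray:
    """Decode a 0/255 (or any grayscale) image to a boolean mask at 128."""
    return as_gray_image(img) >= 128


def write_width_table(profile, path) -> None:
    """Write a width profile as CSV plus a one-line summary CSV.

    The main table has columns ``point_index,row,col,radius_px,diameter_px``;
    the summary file (``<stem>_summary.csv``) holds the point count and the
    mean diameter D.
    """
    if profile.n == 0:
        raise ValidationError("cannot write an empty width profile")
    path = Path(path)
    if not path.parent.is_dir():
        raise InputError(f"output directory does not exist: {path.parent}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["point_index", "row", "col", "radius_px", "diameter_px"])
        for e in profile.entries:
            w.writerow([e.index, e.row, e.col, e.radius, e.diameter])
    summary = path.with_name(path.stem + "_summary" + path.suffix)
    with open(summary, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["n_points", "mean_diameter_px"])
        w.writerow([profile.n, profile.mean_width])
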