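"""End-to-end pipeline: preprocess -> segment -> skeletonize -> edges -> RETC.

:func:`run_pipeline` executes the full chain on one image, writes every
intermediate artifact (enhanced image, mask, skeleton/edge/circle overlays,
width CSV) plus a YAML manifest, and returns a :class:`RunManifest` holding
the mean width D.  :func:`run_batch` maps it over many images and, when
reference widths are supplied, produces the error statistics report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image, ImageDraw

from . import __version__
from .config import PipelineConfig
from .edges import EdgeMap, canny, mask_boundary_edges
from .errors import StageError, ValidationError, VeinWidthError
from .io import mask_to_image, read_gray_image, write_gray_image, write_width_table
from .levelset import segment_vessels
from .preprocess import preprocess_image
from .reference import EvalReport, error_stats
from .retc import WidthProfile, retc_width_profile
from .skeleton import SkeletonMap, prune_spurs, zhang_suen_thin

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "run_batch"]


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, config, artifacts, result."""

    input_path: str
    config: Dict
    outputs: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    mean_width: float = float("nan")
    n_points: int = 0
    version: str = __version__

    def to_dict(self) -> Dict:
        return {
            "input_path": self.input_path,
            "config": self.config,
            "outputs": dict(self.outputs),
            "warnings": list(self.warnings),
            "mean_width": float(self.mean_width),
            "n_points": int(self.n_points),
            "version": self.version,
        }


def _overlay(base: np.ndarray, points, color: Tuple[int, int, int]) -> Image.Image:
    rgb = np.stack([base] * 3, axis=2).astype(np.uint8)
    for r, c in points:
        rgb[r, c] = color
    return Image.fromarray(rgb, mode="RGB")


def _circle_overlay(base: np.ndarray, profile: WidthProfile,
                    every: int = 10) -> Image.Image:
    """Tangent circles drawn at every ``every``-th skeleton point."""
    im = Image.fromarray(np.stack([base] * 3, axis=2).astype(np.uint8), mode="RGB")
    draw = ImageDraw.Draw(im)
    for e in profile.entries[::max(1, every)]:
        bbox = [e.col - e.radius, e.row - e.radius, e.col + e.radius, e.row + e.radius]
        draw.ellipse(bbox, outline=(255, 0, 0))
    return im


def _edges_for_retc(enhanced: np.ndarray, mask: np.ndarray,
                    cfg: PipelineConfig) -> EdgeMap:
    if cfg.edge_source == "mask":
        return mask_boundary_edges(mask, offset=cfg.edge_offset)
    return canny(enhanced, eta=cfg.canny_eta, low=cfg.canny_low,
                 high=cfg.canny_high, relative=not cfg.canny_absolute)


def run_pipeline(input_path, cfg: Optional[PipelineConfig] = None,
                 outdir=None) -> RunManifest:
    """Run the full width-estimation pipeline on one image.

    Any stage failure is re-raised as :class:`StageError` naming the stage;
    artifacts written before the failure are retained.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(input_path=str(input_path), config=cfg.to_dict())

    def save_image(name: str, img_or_pil) -> None:
        if outdir is None:
            return
        path = outdir / name
        if isinstance(img_or_pil, Image.Image):
            img_or_pil.save(path)
        else:
            write_gray_image(img_or_pil, path)
        manifest.outputs[name.split(".")[0]] = str(path)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except VeinWidthError as exc:
            _write_manifest(manifest, outdir)
            raise StageError(name, exc) from exc

    img = stage("read", read_gray_image, input_path)
    enhanced, report = stage("preprocess", preprocess_image, img, cfg)
    save_image("enhanced.png", enhanced)

    mask = stage("segment", segment_vessels, enhanced, sigma=cfg.ls_sigma,
                 eps=cfg.ls_eps, dt=cfg.ls_dt, mu=cfg.ls_mu, lam=cfg.ls_lambda,
                 alpha=cfg.ls_alpha, steps=cfg.ls_steps, min_area=cfg.min_area,
                 keep_components=cfg.keep_components)
    save_image("mask.png", mask_to_image(mask))

    skel = stage("skeletonize", zhang_suen_thin, mask, cfg.max_thin_iters)
    if cfg.prune_spurs > 0:
        skel = stage("skeletonize", prune_spurs, skel, cfg.prune_spurs)
    save_image("skeleton.png", _overlay(enhanced, skel.points, (0, 255, 0)))

    edges = stage("edge_detect", _edges_for_retc, enhanced, mask, cfg)
    save_image("edges.png", _overlay(enhanced, edges.edge_points, (255, 255, 0)))

    profile = stage("retc", retc_width_profile, skel, edges,
                    r_max=cfg.r_max, r_step=cfg.r_step)
    if profile.excluded:
        manifest.warnings.append(
            f"{profile.excluded} skeleton point(s) excluded: no edge within r_max")
    manifest.mean_width = profile.mean_width
    manifest.n_points = profile.n
    save_image("circles.png", _circle_overlay(enhanced, profile))
    if outdir is not None:
        write_width_table(profile, outdir / "widths.csv")
        manifest.outputs["widths"] = str(outdir / "widths.csv")
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: RunManifest, outdir: Optional[Path]) -> None:
    if outdir is None:
        return
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)
    manifest.outputs["manifest"] = str(outdir / "manifest.yaml")


def run_batch(inputs: Sequence, cfg: Optional[PipelineConfig] = None,
              outdir=None, references: Optional[Sequence[float]] = None):
    """Run the pipeline over several images; failures are recorded, not fatal.

    Returns ``(manifests, report)`` where ``report`` is an
    :class:`EvalReport` when ``references`` are given (one per input, matched
    by position; failed images are dropped from the statistics) else None.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValidationError("empty input list")
    if references is not None and len(references) != len(inputs):
        raise ValidationError("references must match inputs one-to-one")
    outdir = Path(outdir) if outdir is not None else None
    manifests: List[Optional[RunManifest]] = []
    failures: List[str] = []
    for i, path in enumerate(inputs):
        sub = outdir / f"image_{i:03d}" if outdir is not None else None
        try:
            manifests.append(run_pipeline(path, cfg, sub))
        except (StageError, VeinWidthError) as exc:
            logger.error("pipeline failed for %s: %s", path, exc)
            failures.append(f"{path}: {exc}")
            manifests.append(None)
    if all(m is None for m in manifests):
        raise ValidationError(f"every input failed: {failures}")
    report: Optional[EvalReport] = None
    if references is not None:
        pairs = [(m.mean_width, ref) for m, ref in zip(manifests, references)
                 if m is not None]
        est, ref = zip(*pairs)
        report = error_stats(est, ref)
    return manifests, report
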