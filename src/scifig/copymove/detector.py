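"""Panel-pairwise copy-move detection and figure-level fusion.

A figure is segmented into panels, text is erased, and every unordered
pair of panels (including each panel with itself) is examined by placing
the two panels side by side on a canvas separated by an invalid gutter —
the single-image NN-field machinery then finds both within-panel and
cross-panel clones.  The Zernike and RGB feature branches each produce a
figure-level mask; the final clone mask fuses them (union by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..panels import crop_panels, segment_panels
from ..textmask import detect_text_regions, erase_regions
from ..types import Box, CopyMoveConfig, FigureRecord, RasterImage, ValidationError, as_gray, as_rgb
from .features import rgb_field, zernike_field
from .patchmatch import patchmatch_nnf
from .postprocess import bidirectional_filter, dlf_postprocess

__all__ = ["CloneReport", "PairResult", "detect_pair", "detect_copy_move", "BRANCHES"]

log = logging.getLogger("scifig")

BRANCHES = ("zernike", "rgb")


@dataclass
class PairResult:
    """Per-branch clone masks of one panel pair."""

    i: int
    j: int
    masks: dict  # branch -> (mask_a, mask_b)


@dataclass
class CloneReport:
    """Figure-level detection result with per-branch provenance."""

    figure_id: str
    final_mask: np.ndarray
    zernike_mask: np.ndarray
    rgb_mask: np.ndarray
    pair_details: list[PairResult] = field(default_factory=list)


def _branch_margin(branch: str, cfg: CopyMoveConfig) -> int:
    return cfg.zernike_radius_px if branch == "zernike" else cfg.rgb_patch_px // 2


def _pair_seed(cfg: CopyMoveConfig, branch: str, i: int, j: int) -> int:
    return (cfg.seed * 7919 + (0 if branch == "zernike" else 1) + 131 * (i * 97 + j)) % (2**31)


def _run_branch(
    canvas: np.ndarray,
    region_valid: np.ndarray,
    branch: str,
    cfg: CopyMoveConfig,
    seed: int,
) -> np.ndarray:
    img = RasterImage(canvas, "canvas")
    if branch == "zernike":
        fld = zernike_field(img, cfg.zernike_radius_px, cfg.zernike_order)
    else:
        fld = rgb_field(img, cfg.rgb_patch_px)
    fld.valid &= region_valid
    nnf = patchmatch_nnf(fld, cfg.pm_iterations, cfg.min_offset_px, seed)
    keep = bidirectional_filter(nnf, cfg.bidir_tol_px)
    keep &= _significant_matches(nnf, cfg.cost_rel_thresh)
    return dlf_postprocess(nnf, keep, cfg)


def _significant_matches(nnf, rel_thresh: float) -> np.ndarray:
    """Gate matches on cost relative to the field's noise floor.

    A verbatim clone reproduces even the pixel noise, so its match cost
    is (near) zero, whereas the best match between two *different*
    near-uniform regions still pays the noise floor — which is what the
    median matched cost over the field estimates.  Without this gate,
    mutually consistent matches between featureless background regions
    survive both the bidirectional and the affine-coherence tests.
    """
    finite = nnf.valid & np.isfinite(nnf.cost)
    if not finite.any():
        return finite
    floor = float(np.median(nnf.cost[finite]))
    if floor <= 0.0:
        return finite
    return finite & (nnf.cost <= rel_thresh * floor)


def _interior(valid: np.ndarray, box: Box, margin: int) -> None:
    """Mark the interior of `box` (eroded by `margin`) valid."""
    if box.height > 2 * margin and box.width > 2 * margin:
        valid[box.r0 + margin : box.r1 - margin, box.c0 + margin : box.c1 - margin] = True


def detect_pair(
    panel_a: RasterImage,
    panel_b: RasterImage | None = None,
    cfg: CopyMoveConfig | None = None,
    branch: str = "fused",
    _pair: tuple[int, int] = (0, 0),
) -> tuple[np.ndarray, np.ndarray]:
    """Clone masks for a pair of (text-erased) panels.

    The panels are laid side by side with a neutral gutter of width
    ``2 * zernike_radius_px`` (gutter and padding pixels are invalid);
    the branch pipeline runs on the canvas and the resulting mask is
    split back into two panel-local masks.  When ``panel_b`` is None or
    the same object (self pair), the single panel is analyzed alone.
    ``branch`` is "zernike", "rgb", or "fused" (union/intersection of
    both per ``cfg.fusion``).
    """
    cfg = cfg or CopyMoveConfig()
    self_pair = panel_b is None or panel_b is panel_a
    branches = BRANCHES if branch == "fused" else (branch,)

    if self_pair:
        canvas_gray = panel_a.pixels
        boxes = [Box(0, 0, panel_a.rows, panel_a.cols)]
        rows, cols = panel_a.rows, panel_a.cols
        color = panel_a.channels == 3
    else:
        gutter = 2 * cfg.zernike_radius_px
        rows = max(panel_a.rows, panel_b.rows)
        cols = panel_a.cols + gutter + panel_b.cols
        color = panel_a.channels == 3 or panel_b.channels == 3
        shape = (rows, cols, 3) if color else (rows, cols)
        canvas_gray = np.full(shape, 255, dtype=np.uint8)
        pa = as_rgb(panel_a.pixels) if color else panel_a.pixels
        pb = as_rgb(panel_b.pixels) if color else panel_b.pixels
        canvas_gray[: panel_a.rows, : panel_a.cols] = pa
        c_b = panel_a.cols + gutter
        canvas_gray[: panel_b.rows, c_b : c_b + panel_b.cols] = pb
        boxes = [
            Box(0, 0, panel_a.rows, panel_a.cols),
            Box(0, c_b, panel_b.rows, c_b + panel_b.cols),
        ]

    out: dict[str, np.ndarray] = {}
    for br in branches:
        margin = _branch_margin(br, cfg)
        region_valid = np.zeros((rows, cols), dtype=bool)
        for b in boxes:
            _interior(region_valid, b, margin)
        try:
            out[br] = _run_branch(
                canvas_gray, region_valid, br, cfg, _pair_seed(cfg, br, *_pair)
            )
        except ValidationError as exc:
            log.warning("pair %s skipped in %s branch: %s", _pair, br, exc)
            out[br] = np.zeros((rows, cols), dtype=bool)

    if branch == "fused":
        combined = (
            out["zernike"] | out["rgb"] if cfg.fusion == "or" else out["zernike"] & out["rgb"]
        )
    else:
        combined = out[branch]

    mask_a = combined[boxes[0].slices()]
    if self_pair:
        return mask_a, mask_a.copy()
    return mask_a, combined[boxes[1].slices()]


def _pair_branch_masks(
    panel_a: RasterImage,
    panel_b: RasterImage | None,
    cfg: CopyMoveConfig,
    pair: tuple[int, int],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    masks = {}
    for br in BRANCHES:
        masks[br] = detect_pair(panel_a, panel_b, cfg, branch=br, _pair=pair)
    return masks


def detect_copy_move(figure: FigureRecord, cfg: CopyMoveConfig | None = None) -> CloneReport:
    """End-to-end clone detection on a figure.

    Panels come from ``figure.panels`` when provided, otherwise from
    :func:`segment_panels` (the whole figure is used as a single panel
    when nothing is found).  Text regions are detected and erased per
    panel, all unordered panel pairs are examined, and per-branch masks
    are assembled by union in figure coordinates.  The final mask fuses
    the Zernike and RGB branches.
    """
    cfg = cfg or CopyMoveConfig()
    img = figure.image
    boxes = list(figure.panels) or segment_panels(img)
    if not boxes:
        boxes = [Box(0, 0, img.rows, img.cols)]
    panels = crop_panels(img, boxes)
    cleaned = []
    for p in panels:
        text = detect_text_regions(p)
        cleaned.append(erase_regions(p, text) if text else p)

    branch_fig = {br: np.zeros(img.shape, dtype=bool) for br in BRANCHES}
    details: list[PairResult] = []
    n = len(cleaned)
    for i in range(n):
        for j in range(i, n):
            pb = None if j == i else cleaned[j]
            masks = _pair_branch_masks(cleaned[i], pb, cfg, (i, j))
            for br, (ma, mb) in masks.items():
                branch_fig[br][boxes[i].slices()] |= ma
                if j != i:
                    branch_fig[br][boxes[j].slices()] |= mb
            details.append(PairResult(i, j, masks))

    final = (
        branch_fig["zernike"] | branch_fig["rgb"]
        if cfg.fusion == "or"
        else branch_fig["zernike"] & branch_fig["rgb"]
    )
    return CloneReport(
        figure_id=figure.id,
        final_mask=final,
        zernike_mask=branch_fig["zernike"],
        rgb_mask=branch_fig["rgb"],
        pair_details=details,
    )
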