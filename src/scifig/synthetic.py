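"""Seeded generator of scientific-figure phantoms with full ground truth.

The generator emulates the imagery the detector is aimed at — western
blot-like band panels, micrograph-like blob panels, multi-panel
composition with label text, planted clones (optionally mirrored or
rotated), and cross-"paper" reuse chains with publication dates — so
that every pipeline stage can be exercised and scored without any
external data.  Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage
from skimage.transform import resize

from .provenance import GraphEdge, GraphNode, ProvenanceGraph
from .types import Box, FigureRecord, RasterImage, ValidationError

__all__ = [
    "SyntheticCase",
    "make_blot_panel",
    "make_micrograph_panel",
    "make_color_panel",
    "compose_figure",
    "plant_clone",
    "make_clone_figure",
    "make_reuse_case",
]

GUTTER_PX = 12
LABEL_STRIP_PX = 14


@dataclass
class SyntheticCase:
    """A set of figures with dates/DOIs plus every ground-truth object."""

    figures: list[FigureRecord]
    truth_masks: dict = field(default_factory=dict)
    truth_boxes: dict = field(default_factory=dict)
    truth_graph: ProvenanceGraph | None = None
    seed: int = 0


def make_blot_panel(
    seed: int,
    lanes: int = 4,
    bands_per_lane: int = 3,
    size: tuple[int, int] = (128, 192),
    return_geometry: bool = False,
):
    """Western-blot-like panel: dark elliptical bands in lanes.

    Light background at 230±10, band cores near intensity 70, Gaussian
    blur sigma 1.5 and additive Gaussian noise sigma 3.  Bands are laid
    out on a lane grid with jitter but never touching, so they remain
    individually resolvable.  ``return_geometry`` additionally returns
    ``{"background": bg, "bands": [(center_row, center_col, semi_axis_r,
    semi_axis_c, depth), ...]}`` describing what was actually drawn, for
    analytic-area oracles.
    """
    rows, cols = size
    if rows < 64 or cols < 64:
        raise ValidationError("blot panel must be at least 64x64")
    rng = np.random.default_rng(seed)
    bg = rng.uniform(220, 240)
    canvas = np.full((rows, cols), bg, dtype=np.float64)
    geometry = []
    if lanes > 0 and bands_per_lane > 0:
        lane_w = cols / lanes
        band_h = rows / (bands_per_lane + 1)
        a_hi = max(3.0, min(6.0, band_h / 3))
        b_hi = max(4.0, min(18.0, lane_w / 2 - 3))
        yy, xx = np.mgrid[0:rows, 0:cols]
        for lane in range(lanes):
            cx = (lane + 0.5) * lane_w
            for band in range(bands_per_lane):
                cy = (band + 1) * band_h + rng.uniform(-3, 3)
                a = rng.uniform(min(3.0, a_hi * 0.8), a_hi)  # semi-axis rows
                b = rng.uniform(min(8.0, b_hi * 0.8), b_hi)  # semi-axis cols
                depth = rng.uniform(140, 165)  # bg - depth ~ band core
                inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
                canvas[inside] = bg - depth
                geometry.append((cy, cx, a, b, depth))
    canvas = ndimage.gaussian_filter(canvas, sigma=1.5)
    canvas += rng.normal(0, 3, canvas.shape)
    panel = np.clip(canvas, 0, 255).astype(np.uint8)
    img = RasterImage(panel, f"blot-{seed}")
    if return_geometry:
        return img, {"background": float(bg), "bands": geometry}
    return img


def make_micrograph_panel(
    seed: int, n_cells: int = 12, size: tuple[int, int] = (128, 128)
) -> RasterImage:
    """Micrograph-like panel: bright cell blobs on a dark textured field.

    Cells are discs of random radius 5-15 px placed with rejection
    sampling so they do not overlap (keeping the planted count
    recoverable by thresholding + labeling); the background is smooth
    dark texture and the whole frame gets Poisson-like shot noise.
    """
    rows, cols = size
    rng = np.random.default_rng(seed)

    def smooth(sigma, std):
        f = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), sigma)
        return f * (std / max(f.std(), 1e-9))

    # two-scale background texture (debris/illumination), as in real
    # micrographs; it also gives keypoint detectors something to hold on to
    base = 50 + smooth(4, 15) + smooth(1.5, 10)
    canvas = np.clip(base, 5, 140)
    centers = []
    attempts = 0
    while len(centers) < n_cells and attempts < 2000:
        attempts += 1
        r = rng.uniform(5, 15)
        cy = rng.uniform(r + 2, rows - r - 2)
        cx = rng.uniform(r + 2, cols - r - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 4) ** 2 for y, x, rr in centers):
            centers.append((cy, cx, r))
    yy, xx = np.mgrid[0:rows, 0:cols]
    for cy, cx, r in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blob = np.exp(-d2 / (2 * (r / 1.8) ** 2))
        canvas = np.maximum(canvas, 60 + rng.uniform(130, 170) * blob)
    noisy = rng.poisson(np.clip(canvas, 0, 255)).astype(np.float64)
    return RasterImage(np.clip(noisy, 0, 255).astype(np.uint8), f"micro-{seed}")


def make_color_panel(seed: int, size: tuple[int, int] = (128, 128)) -> RasterImage:
    """Low-luma-contrast color panel: chroma texture at near-constant luma.

    The two chroma fields are smooth seeded noise along luma-neutral
    color directions, so the panel is rich in RGB structure while its
    grayscale projection is almost flat — the scenario in which
    Zernike-on-luma features are blind and the raw-RGB branch is not.
    """
    rows, cols = size
    rng = np.random.default_rng(seed)
    s = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), sigma=3)
    t = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), sigma=3)
    s *= 40.0 / max(np.abs(s).max(), 1e-9)
    t *= 40.0 / max(np.abs(t).max(), 1e-9)
    # luma-neutral directions under ITU-R 601 weights
    v1 = np.array([1.0, -0.299 / 0.587, 0.0])
    v2 = np.array([0.0, 0.114 / 0.587, -1.0])
    px = 128.0 + s[:, :, None] * v1 + t[:, :, None] * v2
    return RasterImage(np.clip(px, 0, 255).astype(np.uint8), f"color-{seed}")


def _render_label(width: int, text: str) -> np.ndarray:
    """Rasterize a near-black text strip of LABEL_STRIP_PX height."""
    strip = Image.new("L", (width, LABEL_STRIP_PX), color=255)
    draw = ImageDraw.Draw(strip)
    draw.text((2, 1), text, fill=10, font=ImageFont.load_default())
    return np.asarray(strip)


def compose_figure(
    panels: list[RasterImage],
    grid: tuple[int, int],
    label_text: bool = False,
    seed: int = 0,
) -> tuple[RasterImage, list[Box], list[Box]]:
    """Place panels on a white canvas in an ``(nr, nc)`` grid.

    Panels are separated by 12-px gutters; when ``label_text`` is set a
    near-black label strip is rendered above each panel.  Returns the
    figure plus the panel boxes and the rendered-text boxes.
    """
    nr, nc = grid
    if len(panels) > nr * nc:
        raise ValidationError(f"{len(panels)} panels do not fit a {nr}x{nc} grid")
    color = any(p.channels == 3 for p in panels)
    cell_h = max(p.rows for p in panels)
    cell_w = max(p.cols for p in panels)
    strip = LABEL_STRIP_PX if label_text else 0
    rows = GUTTER_PX + nr * (strip + cell_h + GUTTER_PX)
    cols = GUTTER_PX + nc * (cell_w + GUTTER_PX)
    shape = (rows, cols, 3) if color else (rows, cols)
    canvas = np.full(shape, 255, dtype=np.uint8)
    panel_boxes: list[Box] = []
    text_boxes: list[Box] = []
    rng = np.random.default_rng(seed)
    for k, p in enumerate(panels):
        gr, gc = divmod(k, nc)
        r0 = GUTTER_PX + gr * (strip + cell_h + GUTTER_PX) + strip
        c0 = GUTTER_PX + gc * (cell_w + GUTTER_PX)
        px = p.pixels if not color else (
            p.pixels if p.channels == 3 else np.repeat(p.pixels[:, :, None], 3, axis=2)
        )
        canvas[r0 : r0 + p.rows, c0 : c0 + p.cols] = px
        panel_boxes.append(Box(r0, c0, r0 + p.rows, c0 + p.cols))
        if label_text:
            label = f"{chr(65 + k)}{rng.integers(0, 10)}"
            strip_px = _render_label(p.cols, label)
            sr0 = r0 - strip
            if color:
                canvas[sr0 : sr0 + strip, c0 : c0 + p.cols] = strip_px[:, :, None]
            else:
                canvas[sr0 : sr0 + strip, c0 : c0 + p.cols] = strip_px
            ink = np.nonzero(strip_px < 128)
            if len(ink[0]):
                text_boxes.append(
                    Box(
                        sr0 + int(ink[0].min()),
                        c0 + int(ink[1].min()),
                        sr0 + int(ink[0].max()) + 1,
                        c0 + int(ink[1].max()) + 1,
                    )
                )
    return RasterImage(canvas, f"figure-{seed}"), panel_boxes, text_boxes


_TRANSFORMS = ("none", "mirror_h", "rot90", "rot180")


def plant_clone(
    figure: RasterImage,
    src: Box,
    dst_anchor: tuple[int, int],
    transform: str = "none",
    seed: int = 0,
) -> tuple[RasterImage, np.ndarray]:
    """Clone the ``src`` region to ``dst_anchor`` under a rigid transform.

    The destination footprint must lie inside the image and be disjoint
    from the source.  Returns the manipulated figure and the ground
    truth mask, true exactly on source ∪ destination.
    """
    if transform not in _TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    src.check_within(figure.rows, figure.cols)
    block = figure.pixels[src.slices()].copy()
    if transform == "mirror_h":
        block = block[:, ::-1]
    elif transform == "rot90":
        block = np.rot90(block)
    elif transform == "rot180":
        block = np.rot90(block, 2)
    dr0, dc0 = dst_anchor
    dst = Box(dr0, dc0, dr0 + block.shape[0], dc0 + block.shape[1])
    dst.check_within(figure.rows, figure.cols)
    if dst.intersects(src):
        raise ValidationError("clone destination overlaps the source")
    px = figure.pixels.copy()
    px[dst.slices()] = block
    mask = np.zeros((figure.rows, figure.cols), dtype=bool)
    mask[src.slices()] = True
    mask[dst.slices()] = True
    return RasterImage(px, figure.id), mask


def make_clone_figure(
    seed: int, kind: str = "rigid", label_text: bool = False
) -> tuple[FigureRecord, np.ndarray]:
    """One-panel figure with a planted clone and its ground-truth mask.

    ``kind`` selects the study scenario: "rigid" (exact duplication in a
    blot panel), "mirror" (horizontally mirrored duplication in a blot
    panel, which only rotation/mirror-invariant features can match),
    "color" (exact duplication in a low-luma-contrast color panel, which
    only raw-RGB features can match), or "pristine" (no clone at all).
    """
    rng = np.random.default_rng(seed + 10_000)
    if kind == "color":
        panel = make_color_panel(seed, size=(160, 160))
    else:
        panel = make_blot_panel(seed, lanes=3, bands_per_lane=2, size=(160, 160))
    fig, panel_boxes, text_boxes = compose_figure([panel], (1, 1), label_text, seed)
    if kind == "pristine":
        mask = np.zeros(fig.shape, dtype=bool)
        rec = FigureRecord(
            id=f"clone-{kind}-{seed}", image=fig, panels=panel_boxes, text_regions=text_boxes
        )
        return rec, mask
    transform = "mirror_h" if kind == "mirror" else "none"
    pb = panel_boxes[0]
    side = 48
    src = Box(pb.r0 + 12, pb.c0 + 12, pb.r0 + 12 + side, pb.c0 + 12 + side)
    dst = (pb.r1 - side - 12, pb.c1 - side - 12)
    fig, mask = plant_clone(fig, src, dst, transform, seed)
    rec = FigureRecord(
        id=f"clone-{kind}-{seed}", image=fig, panels=panel_boxes, text_regions=text_boxes
    )
    return rec, mask


def _derive_figure(
    parent: RasterImage, new_id: str, rng: np.random.Generator
) -> RasterImage:
    """Crop (>=50% area) + resize (0.8-1.2x) + brightness (±10) + maybe mirror."""
    px = parent.pixels
    rows, cols = px.shape[:2]
    # each generation keeps 64-85% of its parent's area, so overlap (and
    # with it the match count) decays monotonically along a chain while
    # sixth-generation figures still carry enough content to match
    fr = rng.uniform(0.80, 0.92)
    fc = rng.uniform(0.80, 0.92)
    h, w = max(64, int(rows * fr)), max(64, int(cols * fc))
    r0 = rng.integers(0, rows - h + 1)
    c0 = rng.integers(0, cols - w + 1)
    crop = px[r0 : r0 + h, c0 : c0 + w]
    scale = rng.uniform(0.8, 1.2)
    out_shape = (max(64, int(h * scale)), max(64, int(w * scale)))
    if crop.ndim == 3:
        out_shape = out_shape + (3,)
    resized = resize(crop.astype(np.float64), out_shape, anti_aliasing=True)
    resized += rng.uniform(-10, 10)
    if rng.random() < 0.5:
        resized = resized[:, ::-1]
    return RasterImage(np.clip(resized, 0, 255).astype(np.uint8), new_id)


def make_reuse_case(
    n_papers: int, reuses_per_paper: int = 1, seed: int = 0
) -> SyntheticCase:
    """Cross-paper reuse chain with strictly increasing publication dates.

    Paper 0 publishes the root figure; each later paper publishes
    ``reuses_per_paper`` figures derived (crop + resize + brightness
    shift + optional mirror) from the most recent figure of the chain,
    so reuse is derived-of-derived: every generation loses content and
    accumulates resampling relative to the root.  The truth graph
    records exactly the generation edges.
    """
    if n_papers < 2:
        raise ValidationError("need at least two papers")
    rng = np.random.default_rng(seed)
    # one large dense panel: content fills the frame, so any >=50%-area
    # crop window along the chain still holds matchable structure
    root_panels = [make_micrograph_panel(seed * 31 + 1, n_cells=40, size=(288, 288))]
    root_img, root_boxes, _ = compose_figure(root_panels, (1, 1), False, seed)
    base_date = _dt.date(2015, 1, 1)
    figures: list[FigureRecord] = [
        FigureRecord(
            id="fig-p0-0",
            image=RasterImage(root_img.pixels, "fig-p0-0"),
            doi="10.0000/synthetic.0",
            date=base_date,
            panels=root_boxes,
        )
    ]
    edges: list[GraphEdge] = []
    for paper in range(1, n_papers):
        date = base_date + _dt.timedelta(days=90 * paper)
        chain_head = figures[-1]
        for k in range(reuses_per_paper):
            parent = chain_head
            fid = f"fig-p{paper}-{k}"
            img = _derive_figure(parent.image, fid, rng)
            figures.append(
                FigureRecord(id=fid, image=img, doi=f"10.0000/synthetic.{paper}", date=date)
            )
            edges.append(GraphEdge(source=parent.id, target=fid, weight=1))
    nodes = [GraphNode(figure_id=f.id, doi=f.doi, date=f.date) for f in figures]
    return SyntheticCase(
        figures=figures,
        truth_masks={},
        truth_boxes={figures[0].id: root_boxes},
        truth_graph=ProvenanceGraph(nodes=nodes, edges=edges),
        seed=seed,
    )
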