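"""Panel segmentation for multi-panel scientific figures.

Compound figures place panels on a light background separated by
gutters.  A deterministic heuristic binarizes the foreground against the
background intensity, closes small gaps, and takes bounding boxes of the
connected components.  It is interface-compatible with (and replaceable
by) a learned panel detector.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import Box, RasterImage, ValidationError, as_gray

__all__ = ["segment_panels", "boxes_to_mask", "crop_panels"]

_MERGE_GAP_PX = 4


def _box_gap(a: Box, b: Box) -> int:
    """Chebyshev-style gap between two boxes (0 when they overlap)."""
    dr = max(a.r0 - b.r1, b.r0 - a.r1, 0)
    dc = max(a.c0 - b.c1, b.c0 - a.c1, 0)
    return max(dr, dc)


def _merge_close(boxes: list[Box], gap: int) -> list[Box]:
    boxes = list(boxes)
    changed = True
    while changed:
        changed = False
        out: list[Box] = []
        for b in boxes:
            for i, a in enumerate(out):
                if _box_gap(a, b) < gap:
                    out[i] = Box(
                        min(a.r0, b.r0), min(a.c0, b.c0), max(a.r1, b.r1), max(a.c1, b.c1)
                    )
                    changed = True
                    break
            else:
                out.append(b)
        boxes = out
    return boxes


def segment_panels(
    image: RasterImage,
    min_panel_px: int = 32,
    gutter_quantile: float = 0.98,
    dark_background: bool = False,
) -> list[Box]:
    """Split a figure into panel bounding boxes.

    Foreground is whatever is darker than the background intensity, read
    off the ``gutter_quantile`` quantile of the luma histogram (figures
    are assumed light-background; set ``dark_background`` to invert).
    Components are closed over small gaps, boxes closer than 4 px are
    merged, and boxes under ``min_panel_px`` per side are dropped.
    Returns boxes sorted row-major by ``(r0, c0)``; an empty list is a
    valid result for a blank figure.
    """
    gray = as_gray(image.pixels).astype(np.float64)
    if dark_background:
        gray = 255.0 - gray
    bg = np.quantile(gray, gutter_quantile)
    fg = gray < bg - 8.0
    if not fg.any():
        return []
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)), iterations=1)
    labels, n = ndimage.label(fg)
    boxes = []
    for sl_r, sl_c in ndimage.find_objects(labels):
        boxes.append(Box(sl_r.start, sl_c.start, sl_r.stop, sl_c.stop))
    boxes = _merge_close(boxes, _MERGE_GAP_PX)
    boxes = [b for b in boxes if b.height >= min_panel_px and b.width >= min_panel_px]
    return sorted(boxes, key=lambda b: (b.r0, b.c0))


def boxes_to_mask(boxes: list[Box], rows: int, cols: int) -> np.ndarray:
    """Rasterize boxes into a boolean mask (true on the union of boxes)."""
    mask = np.zeros((rows, cols), dtype=bool)
    for b in boxes:
        b.check_within(rows, cols)
        mask[b.slices()] = True
    return mask


def crop_panels(image: RasterImage, boxes: list[Box]) -> list[RasterImage]:
    """Extract each box of the figure as its own :class:`RasterImage`."""
    out = []
    for i, b in enumerate(boxes):
        b.check_within(image.rows, image.cols)
        sl = b.slices()
        out.append(RasterImage(image.pixels[sl].copy(), f"{image.id}/panel{i}"))
    return out
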