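"""Detection and removal of overlaid text.

Text labels on figures generate spurious matches — identical lettering
in two panels looks exactly like a clone — so text is localized and
erased before any feature is extracted.  The default backend is a
self-contained connected-component heuristic; an external OCR engine can
be plugged in to supply word boxes instead.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage

from .types import Box, RasterImage, ValidationError, as_gray

__all__ = ["detect_text_regions", "erase_regions", "register_ocr_backend"]

# Glyph geometry: text components are small, high-contrast against the
# local background, elongated at most 8:1, and made of thin strokes —
# a single 3x3 erosion wipes out a 1-2 px stroke but leaves a core in
# filled shapes such as blot bands or cell bodies, which is what keeps
# the heuristic from erasing the very content the clone detector must
# examine.
_MIN_GLYPH_H = 4
_MAX_GLYPH_H = 32
_MAX_ASPECT = 8.0
_CONTRAST = 120.0

_ocr_backend: Callable[[RasterImage], list[Box]] | None = None


def register_ocr_backend(fn: Callable[[RasterImage], list[Box]] | None) -> None:
    """Install a callable returning word boxes for the "ocr" backend."""
    global _ocr_backend
    _ocr_backend = fn


def _heuristic_boxes(image: RasterImage) -> list[Box]:
    gray = as_gray(image.pixels).astype(np.float64)
    contrast = np.abs(gray - np.median(gray)) >= _CONTRAST
    if not contrast.any():
        return []
    labels, _ = ndimage.label(contrast, structure=np.ones((3, 3)))
    comps = []
    objects = ndimage.find_objects(labels)
    for idx, (sl_r, sl_c) in enumerate(objects, start=1):
        h = sl_r.stop - sl_r.start
        w = sl_c.stop - sl_c.start
        if not (_MIN_GLYPH_H <= h <= _MAX_GLYPH_H):
            continue
        if max(h, w) / min(h, w) > _MAX_ASPECT:
            continue
        comp = labels[sl_r, sl_c] == idx
        if ndimage.binary_erosion(comp).any():
            continue  # has a thick core: band/cell, not lettering
        comps.append(Box(sl_r.start, sl_c.start, sl_r.stop, sl_c.stop))
    # group glyphs into text lines: vertical overlap + horizontal gap
    # no larger than the glyph height
    comps.sort(key=lambda b: (b.r0, b.c0))
    lines: list[Box] = []
    for b in comps:
        for i, a in enumerate(lines):
            v_overlap = min(a.r1, b.r1) - max(a.r0, b.r0)
            h_gap = max(a.c0 - b.c1, b.c0 - a.c1, 0)
            if v_overlap > 0 and h_gap <= max(a.height, b.height):
                lines[i] = Box(min(a.r0, b.r0), min(a.c0, b.c0), max(a.r1, b.r1), max(a.c1, b.c1))
                break
        else:
            lines.append(b)
    return sorted(lines, key=lambda b: (b.r0, b.c0))


def detect_text_regions(image: RasterImage, backend: str = "heuristic") -> list[Box]:
    """Locate suspected text boxes.

    ``backend="heuristic"`` uses the built-in glyph heuristic;
    ``backend="ocr"`` delegates to a registered OCR engine
    (:func:`register_ocr_backend`) and raises a configuration error when
    none is installed.
    """
    if backend == "heuristic":
        return _heuristic_boxes(image)
    if backend == "ocr":
        if _ocr_backend is None:
            raise ValidationError(
                "no OCR backend registered; call register_ocr_backend() or "
                "fall back to backend='heuristic'"
            )
        return _ocr_backend(image)
    raise ValidationError(f"unknown text backend {backend!r}")


def erase_regions(image: RasterImage, boxes: list[Box], fill: str = "median") -> RasterImage:
    """Return a copy with the given boxes filled; other pixels untouched.

    ``fill="median"`` uses the per-channel median intensity of the whole
    image (so erased areas blend with the dominant background rather
    than becoming a uniform alien patch); ``fill="white"`` uses 255.
    """
    if fill not in ("median", "white"):
        raise ValidationError(f"unknown fill {fill!r}")
    px = image.pixels.copy()
    if fill == "white":
        value = 255 if px.ndim == 2 else np.array([255, 255, 255], dtype=np.uint8)
    else:
        value = (
            np.uint8(np.median(px))
            if px.ndim == 2
            else np.median(px.reshape(-1, 3), axis=0).astype(np.uint8)
        )
    for b in boxes:
        b.check_within(image.rows, image.cols)
        px[b.slices()] = value
    return RasterImage(px, image.id)
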