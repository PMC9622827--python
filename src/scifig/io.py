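"""Raster and metadata I/O.

Figures are read from PNG/TIFF/JPEG into 8-bit arrays; 16-bit inputs are
linearly rescaled, palettes expanded to RGB and alpha dropped.  Clone
masks round-trip losslessly through single-channel 0/255 PNG.  A *case*
(a set of figures under analysis together) is described by a JSON array
of ``{"id", "file", "doi", "date"}`` records.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
from PIL import Image

from .types import FigureRecord, RasterImage, ValidationError, validate_mask

__all__ = ["load_image", "save_mask", "load_mask", "load_case", "save_case"]


def load_image(path, id: str | None = None) -> RasterImage:
    """Load a raster figure as an 8-bit :class:`RasterImage`.

    16-bit inputs are rescaled to 8 bit by linear min-max; palette images
    are expanded to RGB; an alpha channel is discarded.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode == "P":
                im = im.convert("RGB")
            elif im.mode == "RGBA":
                im = im.convert("RGB")
            elif im.mode == "LA":
                im = im.convert("L")
            px = np.asarray(im)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read raster file {path}") from exc
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        px = px.astype(np.float64)
        lo, hi = px.min(), px.max()
        px = np.zeros_like(px) if hi == lo else (px - lo) * (255.0 / (hi - lo))
        px = np.round(px).astype(np.uint8)
    if px.size == 0:
        raise ValidationError(f"zero-area image {path}")
    return RasterImage(px, id if id is not None else path.stem)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG (lossless)."""
    mask = validate_mask(mask, mask.shape[:2])
    path = Path(path)
    try:
        Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}") from exc


def load_mask(path) -> np.ndarray:
    """Read a mask PNG back to boolean (any nonzero pixel is True)."""
    img = load_image(path)
    px = img.pixels if img.channels == 1 else img.pixels[:, :, 0]
    return px > 127


def load_case(meta_path) -> list[FigureRecord]:
    """Load a case metadata JSON and its figure files.

    Image paths in the JSON are resolved relative to the JSON file.
    """
    meta_path = Path(meta_path)
    with open(meta_path) as fh:
        records = json.load(fh)
    base = meta_path.parent
    figures = []
    seen: set[str] = set()
    for rec in records:
        fid = rec["id"]
        if fid in seen:
            raise ValidationError(f"duplicate figure id {fid!r} in case")
        seen.add(fid)
        img = load_image(base / rec["file"], id=fid)
        figures.append(
            FigureRecord(
                id=fid,
                image=img,
                doi=rec.get("doi", ""),
                date=rec.get("date"),
            )
        )
    return figures


def save_case(figures: list[FigureRecord], out_dir, meta_name: str = "case.json") -> Path:
    """Write figure PNGs plus the case metadata JSON; returns the JSON path."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for fig in figures:
        fname = f"{fig.id}.png"
        Image.fromarray(fig.image.pixels).save(out_dir / fname)
        records.append(
            {
                "id": fig.id,
                "file": fname,
                "doi": fig.doi,
                "date": fig.date.isoformat() if fig.date else "",
            }
        )
    meta_path = out_dir / meta_name
    with open(meta_path, "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
    return meta_path
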