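"""Core domain types shared by every stage of the pipeline.

Conventions used throughout the package:

* images are ``numpy`` arrays of ``uint8``, shape ``(rows, cols)`` for
  grayscale or ``(rows, cols, 3)`` for RGB;
* binary masks are boolean arrays with the same first two dimensions as
  their source image;
* all pixel coordinates are 0-based, row-major, and boxes are half-open
  intervals ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RasterImage",
    "Box",
    "FigureRecord",
    "CopyMoveConfig",
    "ValidationError",
    "parse_date",
    "as_gray",
    "as_rgb",
    "validate_mask",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class RasterImage:
    """An 8-bit raster figure (or panel) with an identifier.

    ``pixels`` is ``(rows, cols)`` uint8 for grayscale or
    ``(rows, cols, 3)`` uint8 for RGB.  Grayscale images are kept
    single-channel until a stage requires three channels.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise ValidationError(f"image {self.id!r}: pixels must be uint8, got {px.dtype}")
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValidationError(
                f"image {self.id!r}: expected (rows, cols) or (rows, cols, 3), got {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"image {self.id!r}: zero-area image")
        self.pixels = px

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True, order=True)
class Box:
    """Half-open axis-aligned pixel box ``[r0, r1) x [c0, c1)``."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValidationError(f"degenerate box {self!r}")
        if self.r0 < 0 or self.c0 < 0:
            raise ValidationError(f"negative box origin {self!r}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.height * self.width

    def check_within(self, rows: int, cols: int) -> None:
        if self.r1 > rows or self.c1 > cols:
            raise ValidationError(f"box {self} exceeds image {rows}x{cols}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def intersects(self, other: "Box") -> bool:
        return not (
            self.r1 <= other.r0
            or other.r1 <= self.r0
            or self.c1 <= other.c0
            or other.c1 <= self.c0
        )

    def to_dict(self) -> dict:
        return {"r0": self.r0, "c0": self.c0, "r1": self.r1, "c1": self.c1}

    @staticmethod
    def from_dict(d: dict) -> "Box":
        return Box(int(d["r0"]), int(d["c0"]), int(d["r1"]), int(d["c1"]))


def parse_date(value) -> Optional[_dt.date]:
    """Parse an ISO-8601 date; year-only values map to January 1st.

    ``None`` and the empty string mean "date unknown" and return ``None``;
    figures without a date are exempt from the publication-date constraint.
    """
    if value is None or value == "":
        return None
    if isinstance(value, _dt.date):
        return value
    s = str(value).strip()
    if len(s) == 4 and s.isdigit():
        return _dt.date(int(s), 1, 1)
    try:
        return _dt.date.fromisoformat(s)
    except ValueError as exc:
        raise ValidationError(f"unparseable date {value!r}") from exc


@dataclass
class FigureRecord:
    """A figure together with the paper metadata that drives provenance.

    ``panels`` and ``text_regions`` may be pre-populated (e.g. from the
    synthetic generator's ground truth); stages that need them fall back
    to their own detectors when the lists are empty.
    """

    id: str
    image: RasterImage
    doi: str = ""
    date: Optional[_dt.date] = None
    panels: list[Box] = field(default_factory=list)
    text_regions: list[Box] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.date = parse_date(self.date)
        if not self.id:
            raise ValidationError("FigureRecord requires a non-empty id")


@dataclass
class CopyMoveConfig:
    """Tunable parameters of the copy-move detector.

    Defaults follow common practice for dense-field copy-move detection:
    Zernike order 5 on a radius-8 disc (12 magnitude features), 8x8 RGB
    patches, 8 PatchMatch iterations, minimum offset 16 px to suppress
    trivial near-self matches, bidirectional tolerance 2 px, and a
    post-processing chain of median filtering (7 px window), local affine
    residual rejection (4 px^2), 50-px minimum region area and 3-px
    dilation.
    """

    zernike_order: int = 5
    zernike_radius_px: int = 8
    rgb_patch_px: int = 8
    pm_iterations: int = 8
    min_offset_px: int = 16
    bidir_tol_px: int = 2
    median_window_px: int = 7
    dlf_error_thresh: float = 4.0
    min_region_px: int = 50
    dilation_radius_px: int = 3
    cost_rel_thresh: float = 0.25
    seed: int = 0
    fusion: str = "or"  # "or" (union of branch masks) or "and"

    def __post_init__(self) -> None:
        sizes = (
            self.zernike_radius_px,
            self.rgb_patch_px,
            self.pm_iterations,
            self.min_offset_px,
            self.median_window_px,
            self.min_region_px,
        )
        if any(s <= 0 for s in sizes):
            raise ValidationError("all size parameters must be positive")
        if self.min_offset_px <= self.bidir_tol_px:
            raise ValidationError("min_offset_px must exceed bidir_tol_px")
        if self.fusion not in ("or", "and"):
            raise ValidationError("fusion must be 'or' or 'and'")


def as_gray(pixels: np.ndarray) -> np.ndarray:
    """Luma (ITU-R 601) of an image; grayscale passes through as uint8."""
    if pixels.ndim == 2:
        return pixels
    w = np.array([0.299, 0.587, 0.114])
    return np.clip(pixels.astype(np.float64) @ w, 0, 255).astype(np.uint8)


def as_rgb(pixels: np.ndarray) -> np.ndarray:
    """Replicate a grayscale image to three channels; RGB passes through."""
    if pixels.ndim == 3:
        return pixels
    return np.repeat(pixels[:, :, None], 3, axis=2)


def validate_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool or mask.ndim != 2:
        raise ValidationError("mask must be a 2-D boolean array")
    if mask.shape != tuple(shape):
        raise ValidationError(f"mask shape {mask.shape} != image shape {tuple(shape)}")
    return mask
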