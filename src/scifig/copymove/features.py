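"""Dense per-pixel features for the clone search.

Two complementary feature branches are used.  Zernike-moment magnitudes
are invariant to patch rotation and mirroring, which makes them catch
rotated/mirrored band duplications but blind to content whose luma
barely varies.  Raw RGB patch values are sensitive to any intensity or
chroma difference but not transformation-invariant.  The detector fuses
both branches downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial, pi

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from ..types import RasterImage, ValidationError, as_gray, as_rgb

__all__ = ["DenseFeatureField", "zernike_field", "rgb_field", "zernike_kernels"]


@dataclass
class DenseFeatureField:
    """Per-pixel feature vectors plus the validity mask of the margin.

    ``valid`` is false wherever the patch support of a pixel would leave
    the image (a border margin equal to the patch radius).
    """

    features: np.ndarray  # (rows, cols, d)
    valid: np.ndarray  # (rows, cols) bool
    d: int

    def __post_init__(self) -> None:
        if self.features.ndim != 3 or self.features.shape[2] != self.d:
            raise ValidationError("feature array must be (rows, cols, d)")
        if self.valid.shape != self.features.shape[:2]:
            raise ValidationError("valid mask shape mismatch")


def zernike_indices(order: int) -> list[tuple[int, int]]:
    """Moment indices (n, m) with 0 <= m <= n, n - m even, n <= order."""
    return [(n, m) for n in range(order + 1) for m in range(n + 1) if (n - m) % 2 == 0]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coef = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += coef * rho ** (n - 2 * k)
    return out


@lru_cache(maxsize=16)
def zernike_kernels(radius: int, order: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Sampled conjugate Zernike basis kernels on the radius-`radius` disc.

    Returns a complex array of shape ``(len(indices), 2r+1, 2r+1)``; each
    kernel is zero outside the disc, scaled by ``(n+1)/pi`` over the disc
    pixel count, and (for (n, m) != (0, 0)) mean-corrected over the disc
    so a constant patch has exactly zero response.  The disc grid is
    symmetric under 90-degree rotation and mirroring, so moment
    magnitudes computed with these kernels are exactly invariant under
    those patch transforms.
    """
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    x = xx / radius
    y = yy / radius
    rho = np.sqrt(x * x + y * y)
    theta = np.arctan2(y, x)
    disc = rho <= 1.0
    npx = int(disc.sum())
    idx = zernike_indices(order)
    kernels = np.zeros((len(idx), 2 * radius + 1, 2 * radius + 1), dtype=np.complex128)
    for i, (n, m) in enumerate(idx):
        v = _radial_poly(n, m, rho) * np.exp(1j * m * theta)
        k = np.where(disc, np.conj(v), 0) * ((n + 1) / pi / npx)
        if (n, m) != (0, 0):
            k[disc] -= k[disc].mean()
        kernels[i] = k
    return kernels, idx


def zernike_field(image: RasterImage, radius_px: int = 8, order: int = 5) -> DenseFeatureField:
    """Dense Zernike-moment magnitudes |Z_nm| on a sliding circular patch.

    The image is converted to luma and scaled to [0, 1]; each feature
    channel is the magnitude of one moment (n, m), n <= order, computed
    on the disc of ``radius_px`` centered at the pixel.  Deterministic.
    """
    if radius_px < 4:
        raise ValidationError("zernike radius must be >= 4")
    if order > 8:
        raise ValidationError("zernike order must be <= 8")
    gray = as_gray(image.pixels).astype(np.float64) / 255.0
    rows, cols = gray.shape
    if rows < 2 * radius_px + 1 or cols < 2 * radius_px + 1:
        raise ValidationError(
            f"image {rows}x{cols} smaller than Zernike support {2 * radius_px + 1}"
        )
    kernels, idx = zernike_kernels(radius_px, order)
    feats = np.empty((rows, cols, len(idx)), dtype=np.float64)
    for i in range(len(idx)):
        # correlation = convolution with the doubly-flipped kernel
        resp = fftconvolve(gray, kernels[i][::-1, ::-1], mode="same")
        feats[:, :, i] = np.abs(resp)
    valid = np.zeros((rows, cols), dtype=bool)
    valid[radius_px : rows - radius_px, radius_px : cols - radius_px] = True
    return DenseFeatureField(feats, valid, len(idx))


def rgb_field(image: RasterImage, patch_px: int = 8) -> DenseFeatureField:
    """Dense raw-RGB patch features.

    The feature of pixel p is the raveled ``patch_px x patch_px x 3``
    block whose top-left corner is ``p - patch_px/2`` (raw intensities).
    Grayscale inputs are replicated to three channels.
    """
    if patch_px < 4 or patch_px % 2:
        raise ValidationError("rgb patch size must be even and >= 4")
    px = as_rgb(image.pixels)
    rows, cols = px.shape[:2]
    if rows < patch_px or cols < patch_px:
        raise ValidationError(f"image {rows}x{cols} smaller than patch {patch_px}")
    half = patch_px // 2
    d = 3 * patch_px * patch_px
    win = sliding_window_view(px, (patch_px, patch_px), axis=(0, 1))
    # win[i, j] is the block with top-left (i, j); pixel p anchors at p-half
    flat = win.transpose(0, 1, 3, 4, 2).reshape(win.shape[0], win.shape[1], d)
    feats = np.zeros((rows, cols, d), dtype=np.float32)
    feats[half : half + win.shape[0], half : half + win.shape[1]] = flat
    valid = np.zeros((rows, cols), dtype=bool)
    valid[half : half + win.shape[0], half : half + win.shape[1]] = True
    return DenseFeatureField(feats, valid, d)
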