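"""Validation and cleanup of the raw offset field.

Scientific imagery (near-uniform backgrounds, narrow intensity ranges,
repeated band shapes) produces many accidental nearest-neighbor matches.
Two tests separate true clones from them: the match must hold in both
directions, and the surviving offsets must be locally consistent with an
affine motion model (dense linear fitting).  Morphological cleanup then
removes specks and marks both sides of every clone.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
import warnings

from skimage.morphology import dilation, disk, remove_small_objects

from ..types import CopyMoveConfig
from .patchmatch import OffsetField

__all__ = ["bidirectional_filter", "dlf_postprocess"]


def bidirectional_filter(nnf: OffsetField, tol_px: int = 2) -> np.ndarray:
    """Keep pixels whose match holds both ways.

    A pixel p with offset f(p) survives iff its partner q = p + f(p) is
    valid and f(q) is the (approximate) inverse: ||f(q) + f(p)||_inf <=
    ``tol_px``.  A region is declared cloned only when the match from A
    towards B and the match from B towards A agree.
    """
    rows, cols = nnf.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    qr = rr + nnf.dr
    qc = cc + nnf.dc
    inb = (qr >= 0) & (qr < rows) & (qc >= 0) & (qc < cols)
    qr_c = np.clip(qr, 0, rows - 1)
    qc_c = np.clip(qc, 0, cols - 1)
    back_ok = inb & nnf.valid & nnf.valid[qr_c, qc_c]
    err_r = np.abs(nnf.dr[qr_c, qc_c] + nnf.dr)
    err_c = np.abs(nnf.dc[qr_c, qc_c] + nnf.dc)
    return back_ok & (err_r <= tol_px) & (err_c <= tol_px)


def _masked_median(arr: np.ndarray, keep: np.ndarray, window: int) -> np.ndarray:
    """Median of `arr` over a window x window neighborhood restricted to kept pixels."""
    half = window // 2
    a = np.where(keep, arr.astype(np.float64), np.nan)
    a = np.pad(a, half, constant_values=np.nan)
    win = sliding_window_view(a, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows are fine
        med = np.nanmedian(win.reshape(win.shape[0], win.shape[1], -1), axis=2)
    return med


def _affine_residuals(
    dr_f: np.ndarray, dc_f: np.ndarray, keep: np.ndarray, window: int
) -> np.ndarray:
    """Squared residual of each kept pixel against a local affine offset model.

    For the neighborhood of each kept pixel a planar model
    d(r, c) = a + b*dr + c*dc is fit (least squares over kept neighbors)
    to both offset components; the residual is evaluated at the center,
    where the prediction reduces to the intercept.
    """
    half = window // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    m = keep.astype(np.float64)
    ones = np.ones_like(yy, dtype=np.float64)

    def corr(img, kern):
        return ndimage.correlate(img, kern, mode="constant", cval=0.0)

    s0 = corr(m, ones)
    sy = corr(m, yy.astype(np.float64))
    sx = corr(m, xx.astype(np.float64))
    syy = corr(m, (yy * yy).astype(np.float64))
    sxx = corr(m, (xx * xx).astype(np.float64))
    sxy = corr(m, (xx * yy).astype(np.float64))

    M = np.stack(
        [
            np.stack([s0, sy, sx], axis=-1),
            np.stack([sy, syy, sxy], axis=-1),
            np.stack([sx, sxy, sxx], axis=-1),
        ],
        axis=-2,
    )
    M = M + 1e-9 * np.eye(3)

    res2 = np.zeros(keep.shape, dtype=np.float64)
    for comp in (dr_f, dc_f):
        v = np.where(keep, comp, 0.0)
        sv = corr(v, ones)
        syv = corr(v, yy.astype(np.float64))
        sxv = corr(v, xx.astype(np.float64))
        rhs = np.stack([sv, syv, sxv], axis=-1)
        beta = np.linalg.solve(M, rhs[..., None])[..., 0]
        res2 += np.where(keep, (comp - beta[..., 0]) ** 2, 0.0)
    return res2


def dlf_postprocess(
    nnf: OffsetField,
    keep: np.ndarray,
    cfg: CopyMoveConfig | None = None,
    *,
    dilate: bool = True,
) -> np.ndarray:
    """Turn a validated offset field into a clean clone mask.

    Steps: median-filter the offset components over the kept pixels;
    reject pixels whose offsets deviate from the local affine fit by
    more than ``dlf_error_thresh``; remove connected regions smaller
    than ``min_region_px``; mirror every surviving pixel to its partner
    p + f(p) so source and destination are both marked; finally dilate
    (skipped when ``dilate`` is false, exposing the pre-dilation mask,
    which is symmetric under the partner map).
    """
    cfg = cfg or CopyMoveConfig()
    if not keep.any():
        return np.zeros_like(keep)
    w = cfg.median_window_px
    dr_f = _masked_median(nnf.dr, keep, w)
    dc_f = _masked_median(nnf.dc, keep, w)
    good = keep & np.isfinite(dr_f) & np.isfinite(dc_f)
    dr_f = np.where(good, dr_f, 0.0)
    dc_f = np.where(good, dc_f, 0.0)

    res2 = _affine_residuals(dr_f, dc_f, good, 2 * w + 1)
    good &= res2 <= cfg.dlf_error_thresh

    # drop regions with fewer than min_region_px pixels
    good = remove_small_objects(good, max_size=cfg.min_region_px - 1, connectivity=2)

    # mark the partner of every surviving pixel (round the filtered offsets)
    rows, cols = good.shape
    rr, cc = np.nonzero(good)
    qr = rr + np.rint(dr_f[rr, cc]).astype(np.int64)
    qc = cc + np.rint(dc_f[rr, cc]).astype(np.int64)
    inb = (qr >= 0) & (qr < rows) & (qc >= 0) & (qc < cols)
    mask = good.copy()
    mask[qr[inb], qc[inb]] = True

    if dilate and cfg.dilation_radius_px > 0:
        mask = dilation(mask, disk(cfg.dilation_radius_px))
    return mask
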