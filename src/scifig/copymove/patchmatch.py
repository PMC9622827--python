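"""Randomized nearest-neighbor-field search over dense features.

A per-pixel offset field f maps every valid pixel to the most similar
valid pixel elsewhere in the image under squared Euclidean feature
distance, excluding offsets shorter than a minimum length (which would
otherwise match every pixel to its immediate neighborhood).  The search
alternates propagation of the causal neighbors' offsets with a random
search whose window halves each step — the classic randomized NNF
scheme, modified here by the admissibility constraint on the offset
length and by the validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..types import ValidationError
from .features import DenseFeatureField

__all__ = ["OffsetField", "patchmatch_nnf"]


@dataclass
class OffsetField:
    """Integer offset field with per-pixel feature distances.

    For every valid pixel p = (r, c), (r + dr, c + dc) is a valid
    feature location and the offset length is at least the minimum
    offset the field was built with.
    """

    dr: np.ndarray  # (rows, cols) int32
    dc: np.ndarray  # (rows, cols) int32
    valid: np.ndarray  # (rows, cols) bool
    cost: np.ndarray  # (rows, cols) float64

    @property
    def shape(self) -> tuple[int, int]:
        return self.dr.shape


@njit(cache=True, inline="always")
def _dist(feat, r, c, rr, cc, best):
    s = 0.0
    for k in range(feat.shape[2]):
        diff = feat[r, c, k] - feat[rr, cc, k]
        s += diff * diff
        if s >= best:
            return s
    return s


@njit(cache=True)
def _pm_core(feat, valid, iterations, min_off, seed):
    rows, cols = valid.shape
    np.random.seed(seed)
    dr = np.zeros((rows, cols), np.int32)
    dc = np.zeros((rows, cols), np.int32)
    cost = np.full((rows, cols), np.inf)
    ok = np.zeros((rows, cols), np.bool_)
    min2 = min_off * min_off

    # --- seeded random initialization over admissible offsets
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            found = False
            for _ in range(64):
                rr = np.random.randint(0, rows)
                cc = np.random.randint(0, cols)
                if valid[rr, cc] and (rr - r) ** 2 + (cc - c) ** 2 >= min2:
                    dr[r, c] = rr - r
                    dc[r, c] = cc - c
                    cost[r, c] = _dist(feat, r, c, rr, cc, np.inf)
                    found = True
                    break
            if not found:  # deterministic fallback scan
                for rr in range(rows):
                    for cc in range(cols):
                        if valid[rr, cc] and (rr - r) ** 2 + (cc - c) ** 2 >= min2:
                            dr[r, c] = rr - r
                            dc[r, c] = cc - c
                            cost[r, c] = _dist(feat, r, c, rr, cc, np.inf)
                            found = True
                            break
                    if found:
                        break
            ok[r, c] = found

    # --- alternating propagation + shrinking random search
    wmax = rows if rows > cols else cols
    for it in range(iterations):
        if it % 2 == 0:
            r_start, r_stop, c_start, c_stop, step = 0, rows, 0, cols, 1
        else:
            r_start, r_stop, c_start, c_stop, step = rows - 1, -1, cols - 1, -1, -1
        for r in range(r_start, r_stop, step):
            for c in range(c_start, c_stop, step):
                if not ok[r, c]:
                    continue
                best = cost[r, c]
                bdr = dr[r, c]
                bdc = dc[r, c]
                # propagation from the two causal neighbors: zero-order
                # (copy the neighbor's offset) and first-order (linear
                # prediction of the target from two collinear neighbors,
                # which follows affine maps such as mirrors/rotations
                # whose offset is not locally constant)
                for (sr, sc) in ((step, 0), (0, step)):
                    nr = r - sr
                    nc = c - sc
                    if not (0 <= nr < rows and 0 <= nc < cols and ok[nr, nc]):
                        continue
                    for order in range(2):
                        if order == 0:
                            rr = r + dr[nr, nc]
                            cc = c + dc[nr, nc]
                        else:
                            n2r = nr - sr
                            n2c = nc - sc
                            if not (0 <= n2r < rows and 0 <= n2c < cols and ok[n2r, n2c]):
                                continue
                            # target(p) ~ target(n) + (target(n) - target(n2))
                            rr = 2 * (nr + dr[nr, nc]) - (n2r + dr[n2r, n2c])
                            cc = 2 * (nc + dc[nr, nc]) - (n2c + dc[n2r, n2c])
                        if 0 <= rr < rows and 0 <= cc < cols and valid[rr, cc]:
                            cdr = rr - r
                            cdc = cc - c
                            if cdr * cdr + cdc * cdc >= min2:
                                d = _dist(feat, r, c, rr, cc, best)
                                if d < best:
                                    best = d
                                    bdr = cdr
                                    bdc = cdc
                # random search: a few global restarts, then a window
                # halving around the current best target
                for _ in range(4):
                    rr = np.random.randint(0, rows)
                    cc = np.random.randint(0, cols)
                    if valid[rr, cc]:
                        cdr = rr - r
                        cdc = cc - c
                        if cdr * cdr + cdc * cdc >= min2:
                            d = _dist(feat, r, c, rr, cc, best)
                            if d < best:
                                best = d
                                bdr = cdr
                                bdc = cdc
                w = wmax // 2
                while w >= 1:
                    rr = r + bdr + np.random.randint(-w, w + 1)
                    cc = c + bdc + np.random.randint(-w, w + 1)
                    if 0 <= rr < rows and 0 <= cc < cols and valid[rr, cc]:
                        cdr = rr - r
                        cdc = cc - c
                        if cdr * cdr + cdc * cdc >= min2:
                            d = _dist(feat, r, c, rr, cc, best)
                            if d < best:
                                best = d
                                bdr = cdr
                                bdc = cdc
                    w //= 2
                dr[r, c] = bdr
                dc[r, c] = bdc
                cost[r, c] = best

    return dr, dc, cost, ok


def patchmatch_nnf(
    field: DenseFeatureField,
    iterations: int = 8,
    min_offset_px: int = 16,
    seed: int = 0,
) -> OffsetField:
    """Approximate nearest-neighbor field over a dense feature field.

    Deterministic given ``seed``.  Pixels for which no admissible offset
    exists (no valid partner at distance >= ``min_offset_px``) are marked
    invalid in the output; if that happens for *every* valid pixel a
    :class:`ValidationError` is raised.
    """
    valid = np.ascontiguousarray(field.valid)
    rows, cols = valid.shape
    if min_offset_px >= max(rows, cols):
        raise ValidationError("min_offset_px must be smaller than the image extent")
    if not valid.any():
        raise ValidationError("feature field has no valid pixels")
    feat = np.ascontiguousarray(field.features)
    dr, dc, cost, ok = _pm_core(feat, valid, iterations, min_offset_px, seed)
    if valid.any() and not ok.any():
        raise ValidationError(
            f"no admissible offset of length >= {min_offset_px} px exists"
        )
    cost = np.where(ok, cost, np.inf)
    return OffsetField(dr=dr, dc=dc, valid=ok, cost=cost)
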