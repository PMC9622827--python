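"""Mirror-aware keypoint description and vote-based image ranking.

Every figure is mapped to up to ``n_points`` keypoint descriptors plus
the same number extracted from its horizontally mirrored version —
RootSIFT descriptors are rotation- and scale-invariant but do not cope
with mirroring, which is a common form of figure reuse, so the mirrored
view is indexed alongside.  A flat (exact) L2 inverted-file index stores
all descriptors of a case; querying retrieves the k nearest stored
descriptors for each query descriptor and each retrieval casts one vote
for its source figure.  Figures sorted by votes form the output rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT, hessian_matrix_det

from .types import Box, FigureRecord, RasterImage, ValidationError, as_gray

__all__ = [
    "Keypoint",
    "InvertedIndex",
    "Rank",
    "root_sift",
    "describe_figure",
    "build_index",
    "query_rank",
]


@dataclass(frozen=True)
class Keypoint:
    """A detected interest point; mirrored keypoints carry coordinates
    in the mirrored frame."""

    row: float
    col: float
    scale: float
    response: float
    mirrored: bool
    figure_id: str


@dataclass
class Rank:
    """Ordered retrieval result: (figure_id, votes), votes non-increasing."""

    query_id: str
    entries: list[tuple[str, int]] = field(default_factory=list)


def root_sift(raw: np.ndarray) -> np.ndarray:
    """RootSIFT transform: L1-normalize then take element-wise square root.

    The resulting vector has unit Euclidean norm, so L2 distances
    between RootSIFT descriptors emulate the Hellinger kernel on the
    underlying histograms.  An all-zero input maps to all-zero.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if (raw < 0).any():
        raise ValidationError("descriptor components must be non-negative")
    total = raw.sum()
    if total == 0:
        return np.zeros_like(raw)
    return np.sqrt(raw / total)


def _sift_detector(gray: np.ndarray):
    """Default detector: SIFT keypoints re-scored by the Hessian determinant.

    Returns (positions Nx2 (row, col), scales N, responses N,
    descriptors Nx128 non-negative).  The determinant-of-Hessian
    response at each keypoint's scale provides the corner-relevance
    score used to keep the strongest points.
    """
    s = SIFT()
    try:
        s.detect_and_extract(gray)
    except RuntimeError:
        return (np.empty((0, 2)), np.empty(0), np.empty(0), np.empty((0, 128)))
    pos = s.keypoints.astype(np.float64)
    sigmas = s.sigmas
    responses = np.zeros(len(pos))
    for sig in np.unique(sigmas):
        det = hessian_matrix_det(gray, sigma=float(sig))
        sel = sigmas == sig
        rr = np.clip(np.round(pos[sel, 0]).astype(int), 0, gray.shape[0] - 1)
        cc = np.clip(np.round(pos[sel, 1]).astype(int), 0, gray.shape[1] - 1)
        responses[sel] = np.abs(det[rr, cc])
    return pos, s.scales.astype(np.float64), responses, s.descriptors.astype(np.float64)


def _in_boxes(r: float, c: float, boxes: list[Box]) -> bool:
    return any(b.r0 <= r < b.r1 and b.c0 <= c < b.c1 for b in boxes)


def describe_figure(
    figure: FigureRecord,
    n_points: int = 500,
    detector=None,
) -> list[tuple[Keypoint, np.ndarray]]:
    """Keypoints + RootSIFT descriptors of a figure and its mirror.

    Up to ``n_points`` keypoints are kept per view (plain and
    horizontally mirrored), selected by descending detector response
    after discarding keypoints inside ``figure.text_regions`` (text
    boxes are mirrored for the mirrored view).  Featureless figures
    yield fewer (possibly zero) points.
    """
    img = figure.image
    if min(img.rows, img.cols) < 32:
        raise ValidationError("figure must be at least 32 px per side")
    detect = detector or _sift_detector
    gray = as_gray(img.pixels).astype(np.float64) / 255.0
    out: list[tuple[Keypoint, np.ndarray]] = []
    for mirrored in (False, True):
        view = gray[:, ::-1] if mirrored else gray
        boxes = (
            [Box(b.r0, img.cols - b.c1, b.r1, img.cols - b.c0) for b in figure.text_regions]
            if mirrored
            else figure.text_regions
        )
        pos, scales, responses, descs = detect(np.ascontiguousarray(view))
        keep = [i for i in range(len(pos)) if not _in_boxes(pos[i, 0], pos[i, 1], boxes)]
        keep.sort(key=lambda i: -responses[i])
        for i in keep[:n_points]:
            kp = Keypoint(
                row=float(pos[i, 0]),
                col=float(pos[i, 1]),
                scale=float(scales[i]),
                response=float(responses[i]),
                mirrored=mirrored,
                figure_id=figure.id,
            )
            out.append((kp, root_sift(descs[i])))
    return out


class InvertedIndex:
    """Flat exact-L2 descriptor index with per-entry figure back-pointers.

    Every stored descriptor carries (figure_id, mirrored); a k-NN lookup
    therefore resolves directly to source figures, which is what makes
    vote aggregation per figure possible ("inverted file").  Search is
    exhaustive and exact; ties are broken by insertion order.
    """

    def __init__(self) -> None:
        self._chunks: list[np.ndarray] = []
        self._figure_ids: list[str] = []
        self._mirrored: list[bool] = []
        self._matrix: np.ndarray | None = None

    def add_figure(self, figure_id: str, descriptors: list[np.ndarray], mirrored_flags) -> None:
        if figure_id in set(self._figure_ids):
            raise ValidationError(f"duplicate figure id {figure_id!r} in index")
        for d, m in zip(descriptors, mirrored_flags):
            self._chunks.append(np.asarray(d, dtype=np.float64))
            self._figure_ids.append(figure_id)
            self._mirrored.append(bool(m))
        self._matrix = None

    def __len__(self) -> int:
        return len(self._figure_ids)

    @property
    def figure_ids(self) -> list[str]:
        return list(self._figure_ids)

    def _mat(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = (
                np.vstack(self._chunks) if self._chunks else np.empty((0, 128))
            )
        return self._matrix

    def search(self, queries: np.ndarray, k: int, exclude_figure: str | None = None):
        """Exact k-NN: returns (distances, entry indices), each (nq, k').

        Entries belonging to ``exclude_figure`` are skipped without
        consuming a neighbor slot.  ``k'`` may be smaller than ``k``
        when the index holds fewer eligible entries.
        """
        mat = self._mat()
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        if len(self) == 0 or len(queries) == 0:
            return np.empty((len(queries), 0)), np.empty((len(queries), 0), dtype=int)
        dist = cdist(queries, mat)
        if exclude_figure is not None:
            excl = np.array([fid == exclude_figure for fid in self._figure_ids])
            dist[:, excl] = np.inf
        order = np.argsort(dist, axis=1, kind="stable")
        eligible = int(np.isfinite(dist[0]).sum()) if len(dist) else 0
        k = min(k, eligible)
        idx = order[:, :k]
        return np.take_along_axis(dist, idx, axis=1), idx

    def entry_figure(self, idx: int) -> str:
        return self._figure_ids[idx]


def build_index(figures: list[FigureRecord], n_points: int = 500) -> InvertedIndex:
    """Index all descriptors of all figures (ids must be unique)."""
    ids = [f.id for f in figures]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate figure ids")
    index = InvertedIndex()
    for fig in figures:
        pairs = describe_figure(fig, n_points=n_points)
        index.add_figure(
            fig.id, [d for _, d in pairs], [kp.mirrored for kp, _ in pairs]
        )
    return index


def query_rank(
    index: InvertedIndex,
    query: FigureRecord,
    k_nn: int = 8,
    rank_cap: int = 10,
    n_points: int = 500,
) -> Rank:
    """Vote-based ranking of indexed figures against a query figure.

    Each query descriptor retrieves its ``k_nn`` nearest stored entries
    (entries of the query's own figure are skipped) and each retrieval
    adds one vote to its source figure.  Figures are sorted by votes
    descending, ties by ascending summed neighbor distance then
    lexicographic id, truncated to ``rank_cap``.
    """
    if len(index) == 0:
        raise ValidationError("cannot query an empty index")
    pairs = describe_figure(query, n_points=n_points)
    if not pairs:
        return Rank(query_id=query.id, entries=[])
    descs = np.vstack([d for _, d in pairs])
    dists, idxs = index.search(descs, k_nn, exclude_figure=query.id)
    votes: dict[str, int] = {}
    dist_sum: dict[str, float] = {}
    for row_d, row_i in zip(dists, idxs):
        for d, i in zip(row_d, row_i):
            fid = index.entry_figure(int(i))
            votes[fid] = votes.get(fid, 0) + 1
            dist_sum[fid] = dist_sum.get(fid, 0.0) + float(d)
    ordered = sorted(votes, key=lambda f: (-votes[f], dist_sum[f], f))
    return Rank(query_id=query.id, entries=[(f, votes[f]) for f in ordered[:rank_cap]])
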