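"""Provenance-graph construction over a set of figures.

Pairs of figures are matched through geometrically consistent keypoint
correspondences (mutual nearest neighbors + ratio test, verified by an
affine model under seeded RANSAC).  The pairwise inlier counts fill a
symmetric adjacency matrix; Kruskal's maximum-spanning-forest algorithm
extracts the strongest acyclic backbone, and each chosen edge is
oriented from the earlier-published figure to the later one — a figure
can only donate content to figures published after it.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from skimage.measure import ransac
from skimage.transform import AffineTransform

from .retrieval import describe_figure
from .types import FigureRecord, ValidationError, parse_date

__all__ = [
    "GeometricMatch",
    "AdjacencyMatrix",
    "GraphNode",
    "GraphEdge",
    "ProvenanceGraph",
    "match_pair",
    "build_adjacency",
    "span_and_orient",
    "export_graph",
    "import_graph",
]


@dataclass
class GeometricMatch:
    """Inlier correspondences between two figures under one affine model.

    ``transform`` holds the six affine parameters (first two rows of the
    homogeneous matrix, x-y convention, mapping A to B) or None when no
    model was found.  Each inlier is ((row, col) in A, (row, col) in B,
    mirrored) where mirrored marks a plain-vs-mirrored-view match.
    """

    inliers: list = field(default_factory=list)
    count: int = 0
    transform: np.ndarray | None = None


@dataclass
class AdjacencyMatrix:
    """Symmetric pairwise inlier counts with zero diagonal."""

    counts: np.ndarray
    figure_ids: list[str]
    dates: list

    def __post_init__(self) -> None:
        n = len(self.figure_ids)
        if self.counts.shape != (n, n):
            raise ValidationError("adjacency shape mismatch")
        if (self.counts != self.counts.T).any() or np.diag(self.counts).any():
            raise ValidationError("adjacency must be symmetric with zero diagonal")


@dataclass(frozen=True)
class GraphNode:
    figure_id: str
    doi: str = ""
    date: _dt.date | None = None


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    weight: int = 0


@dataclass
class ProvenanceGraph:
    """Directed acyclic forest: edges point from older to newer figures."""

    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)


def _original_frame_coords(kp, cols: int) -> tuple[float, float]:
    """Keypoint coordinates in the un-mirrored frame of its figure."""
    return (kp.row, cols - 1 - kp.col) if kp.mirrored else (kp.row, kp.col)


def match_pair(
    a: FigureRecord,
    b: FigureRecord,
    n_points: int = 2000,
    ratio: float = 0.8,
    ransac_tol_px: float = 5.0,
    ransac_iters: int = 1000,
    seed: int = 0,
) -> GeometricMatch:
    """Geometrically consistent interest-point matches between two figures.

    Both figures are described with mirror augmentation (text regions
    excluded); tentative matches are mutual nearest neighbors passing
    the ratio test; an affine transform is then estimated by seeded
    RANSAC and the inliers within ``ransac_tol_px`` of the model are
    counted.  Fewer than 4 tentative matches yields count 0.
    """
    pa = describe_figure(a, n_points=n_points)
    pb = describe_figure(b, n_points=n_points)
    return _verify_match(
        pa, pb, a.image.cols, b.image.cols, ratio, ransac_tol_px, ransac_iters, seed
    )


def _verify_match(
    pa, pb, cols_a: int, cols_b: int, ratio, ransac_tol_px, ransac_iters, seed
) -> GeometricMatch:
    if not pa or not pb:
        return GeometricMatch()
    da = np.vstack([d for _, d in pa])
    db = np.vstack([d for _, d in pb])
    dist = cdist(da, db)
    nn_ab = np.argmin(dist, axis=1)
    nn_ba = np.argmin(dist, axis=0)
    tentative = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i:
            continue
        d_sorted = np.partition(dist[i], 1) if dist.shape[1] > 1 else None
        if d_sorted is not None:
            d1, d2 = d_sorted[0], d_sorted[1]
            if d2 > 0 and d1 >= ratio * d2:
                continue
            if d2 == 0:  # ambiguous repeated structure
                continue
        tentative.append((i, int(j)))
    if len(tentative) < 4:
        return GeometricMatch()

    kps_a = [pa[i][0] for i, _ in tentative]
    kps_b = [pb[j][0] for _, j in tentative]
    src = np.array(
        [_original_frame_coords(kp, cols_a)[::-1] for kp in kps_a]
    )  # (x, y)
    dst = np.array([_original_frame_coords(kp, cols_b)[::-1] for kp in kps_b])
    try:
        model, inl = ransac(
            (src, dst),
            AffineTransform,
            min_samples=3,
            residual_threshold=ransac_tol_px,
            max_trials=ransac_iters,
            rng=seed,
        )
    except ValueError:
        return GeometricMatch()
    if model is None or inl is None or not inl.any():
        return GeometricMatch()
    inliers = [
        (
            _original_frame_coords(kps_a[t], cols_a),
            _original_frame_coords(kps_b[t], cols_b),
            kps_a[t].mirrored != kps_b[t].mirrored,
        )
        for t in np.nonzero(inl)[0]
    ]
    return GeometricMatch(
        inliers=inliers, count=len(inliers), transform=model.params[:2].ravel()
    )


def build_adjacency(
    figures: list[FigureRecord], min_inliers: int = 8, **match_kwargs
) -> AdjacencyMatrix:
    """Pairwise inlier counts over all unordered figure pairs.

    Entries below ``min_inliers`` are zeroed so isolated noise matches
    never enter the spanning forest.
    """
    ids = [f.id for f in figures]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate figure ids")
    if len(figures) < 2:
        raise ValidationError("need at least two figures")
    n_points = match_kwargs.pop("n_points", 2000)
    ratio = match_kwargs.pop("ratio", 0.8)
    tol = match_kwargs.pop("ransac_tol_px", 5.0)
    iters = match_kwargs.pop("ransac_iters", 1000)
    seed = match_kwargs.pop("seed", 0)
    if match_kwargs:
        raise TypeError(f"unknown match parameters {sorted(match_kwargs)}")
    described = [describe_figure(f, n_points=n_points) for f in figures]
    n = len(figures)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m = _verify_match(
                described[i], described[j],
                figures[i].image.cols, figures[j].image.cols,
                ratio, tol, iters, seed,
            )
            if m.count >= min_inliers:
                counts[i, j] = counts[j, i] = m.count
    return AdjacencyMatrix(counts=counts, figure_ids=ids, dates=[f.date for f in figures])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def span_and_orient(adj: AdjacencyMatrix, dois: dict[str, str] | None = None) -> ProvenanceGraph:
    """Maximum-weight spanning forest, oriented by publication date.

    Kruskal over the nonzero entries (edges sorted by descending
    weight, ties by lexicographic id pair); each chosen edge points
    from the earlier-dated figure to the later-dated one.  Equal or
    missing dates orient by ascending figure id.  Isolated figures
    appear as singleton nodes.
    """
    ids = adj.figure_ids
    dates = [parse_date(d) for d in adj.dates]
    dois = dois or {}
    n = len(ids)
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            w = int(adj.counts[i, j])
            if w > 0:
                a, b = sorted((ids[i], ids[j]))
                cand.append((w, a, b, i, j))
    cand.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = _UnionFind(n)
    edges: list[GraphEdge] = []
    for w, _, _, i, j in cand:
        if not uf.union(i, j):
            continue
        di, dj = dates[i], dates[j]
        if di is not None and dj is not None and di != dj:
            src, dst = (i, j) if di < dj else (j, i)
        else:
            src, dst = (i, j) if ids[i] < ids[j] else (j, i)
        edges.append(GraphEdge(source=ids[src], target=ids[dst], weight=w))
    nodes = [
        GraphNode(figure_id=fid, doi=dois.get(fid, ""), date=dates[k])
        for k, fid in enumerate(ids)
    ]
    return ProvenanceGraph(nodes=nodes, edges=edges)


def export_graph(g: ProvenanceGraph, path) -> None:
    """Write a graph as JSON with deterministic ordering."""
    payload = {
        "nodes": [
            {
                "id": nd.figure_id,
                "doi": nd.doi,
                "date": nd.date.isoformat() if nd.date else "",
            }
            for nd in sorted(g.nodes, key=lambda nd: nd.figure_id)
        ],
        "edges": [
            {"source": e.source, "target": e.target, "weight": e.weight}
            for e in sorted(g.edges, key=lambda e: (e.source, e.target))
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def import_graph(path) -> ProvenanceGraph:
    """Read a graph JSON; malformed files raise with line information."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(
                f"malformed graph JSON {path}: line {exc.lineno}: {exc.msg}"
            ) from exc
    nodes = [
        GraphNode(figure_id=nd["id"], doi=nd.get("doi", ""), date=parse_date(nd.get("date")))
        for nd in payload.get("nodes", [])
    ]
    edges = [
        GraphEdge(source=e["source"], target=e["target"], weight=int(e.get("weight", 0)))
        for e in payload.get("edges", [])
    ]
    return ProvenanceGraph(nodes=nodes, edges=edges)
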