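"""Evaluation metrics for masks, ranks and provenance graphs.

Conventions for degenerate inputs: comparisons of two empty objects
(empty masks, empty graphs) score 1, so pristine-figure evaluations are
well defined; a nonempty prediction against an empty truth (or vice
versa) scores 0.
"""

from __future__ import annotations

import numpy as np

from .types import ValidationError

__all__ = ["iou", "pixel_f1", "precision_at_n", "graph_overlap"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (1 when both empty)."""
    _check_shapes(a, b)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def pixel_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pixel-wise F1 (harmonic mean of precision and recall).

    Returns 1 when both masks are empty and 0 when exactly one is.
    """
    _check_shapes(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    if tp == fp == fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def precision_at_n(rank, relevant, n: int) -> float:
    """Fraction of the top-``n`` ranked figures that are relevant.

    The denominator is ``n`` even when the rank is shorter (missing
    slots count as non-relevant retrievals).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    relevant = set(relevant)
    entries = rank.entries if hasattr(rank, "entries") else rank
    top = [e[0] if isinstance(e, tuple) else e.figure_id for e in entries[:n]]
    return sum(1 for fid in top if fid in relevant) / n


def _undirected_edges(g) -> set:
    return {frozenset((e["source"], e["target"])) if isinstance(e, dict) else
            frozenset((e.source, e.target)) for e in g.edges}


def _node_ids(g) -> set:
    return {n["figure_id"] if isinstance(n, dict) else n.figure_id for n in g.nodes}


def graph_overlap(g, h) -> tuple[float, float, float]:
    """Vertex, edge and combined overlap F-measures between two graphs.

    Edges are compared as unordered id pairs (direction ignored).
    VO = 2|Vg ∩ Vh| / (|Vg| + |Vh|), EO likewise on edges, and
    VEO = 2(|V∩| + |E∩|) / (|Vg| + |Eg| + |Vh| + |Eh|).  Empty
    denominators score 1.
    """
    vg, vh = _node_ids(g), _node_ids(h)
    eg, eh = _undirected_edges(g), _undirected_edges(h)
    vo = 1.0 if not (vg or vh) else 2 * len(vg & vh) / (len(vg) + len(vh))
    eo = 1.0 if not (eg or eh) else 2 * len(eg & eh) / (len(eg) + len(eh))
    denom = len(vg) + len(eg) + len(vh) + len(eh)
    veo = 1.0 if denom == 0 else 2 * (len(vg & vh) + len(eg & eh)) / denom
    return vo, eo, veo
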