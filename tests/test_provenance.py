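"""Geometric matching, dated adjacency and spanning-forest orientation."""

import datetime

import numpy as np
import networkx as nx
import pytest

from conftest import micrograph_figure
from scifig.provenance import (
    AdjacencyMatrix,
    GraphEdge,
    GraphNode,
    ProvenanceGraph,
    build_adjacency,
    export_graph,
    import_graph,
    match_pair,
    span_and_orient,
)
from scifig.retrieval import describe_figure
from scifig.synthetic import make_reuse_case
from scifig.types import FigureRecord, RasterImage, ValidationError


class TestMatchPair:
    def test_self_match_is_near_total_with_identity_transform(self):
        fig = micrograph_figure(7)
        usable = len(describe_figure(fig, n_points=2000))
        m = match_pair(fig, fig)
        assert m.count >= 0.8 * usable
        identity = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        assert np.abs(m.transform - identity).max() < 0.05

    def test_mirrored_crop_matches_through_mirror_augmentation(self):
        fig = micrograph_figure(8)
        px = fig.image.pixels
        crop = np.ascontiguousarray(px[10:118, 12:120][:, ::-1])
        other = FigureRecord(id="mirror-crop", image=RasterImage(crop, "mc"))
        m = match_pair(fig, other)
        assert m.count >= 20
        mirrored_frac = sum(1 for *_, mflag in m.inliers if mflag) / m.count
        assert mirrored_frac > 0.5

    def test_unrelated_noise_figures_barely_match(self):
        a = FigureRecord(
            id="n1",
            image=RasterImage(
                np.random.default_rng(1).integers(0, 256, (128, 128), dtype=np.uint8), "n1"
            ),
        )
        b = FigureRecord(
            id="n2",
            image=RasterImage(
                np.random.default_rng(2).integers(0, 256, (128, 128), dtype=np.uint8), "n2"
            ),
        )
        assert match_pair(a, b).count < 8


class TestBuildAdjacency:
    def test_identical_figures_give_symmetric_positive_entry(self):
        a = micrograph_figure(9, "a")
        b = FigureRecord(id="b", image=RasterImage(a.image.pixels.copy(), "b"))
        adj = build_adjacency([a, b])
        assert adj.counts[0, 1] == adj.counts[1, 0] > 0
        assert adj.counts[0, 0] == adj.counts[1, 1] == 0

    def test_chain_counts_decay_with_generation_distance(self):
        case = make_reuse_case(3, 1, seed=1)
        adj = build_adjacency(case.figures)
        assert adj.counts[0, 1] > 0 and adj.counts[1, 2] > 0
        assert adj.counts[0, 2] <= adj.counts[0, 1]

    def test_duplicate_ids_rejected(self):
        a = micrograph_figure(9, "same")
        b = micrograph_figure(10, "same")
        with pytest.raises(ValidationError):
            build_adjacency([a, b])


def _adj(counts, ids, dates):
    return AdjacencyMatrix(counts=np.array(counts), figure_ids=ids, dates=dates)


class TestSpanAndOrient:
    def test_two_dated_figures_force_orientation(self):
        adj = _adj(
            [[0, 30], [30, 0]], ["A", "B"],
            [datetime.date(2014, 1, 1), datetime.date(2015, 1, 1)],
        )
        g = span_and_orient(adj)
        assert [(e.source, e.target, e.weight) for e in g.edges] == [("A", "B", 30)]

    def test_triangle_keeps_two_heaviest_edges(self):
        adj = _adj(
            [[0, 10, 3], [10, 0, 8], [3, 8, 0]], ["A", "B", "C"], [None, None, None]
        )
        g = span_and_orient(adj)
        undirected = {frozenset((e.source, e.target)) for e in g.edges}
        assert undirected == {frozenset("AB"), frozenset("BC")}
        assert sum(e.weight for e in g.edges) == 18

    def test_matches_networkx_maximum_spanning_forest_weight(self, rng):
        """Total forest weight equals the networkx maximum spanning tree's."""
        for trial in range(10):
            n = int(rng.integers(3, 9))
            counts = rng.integers(0, 40, (n, n))
            counts = np.triu(counts, 1)
            counts = counts + counts.T
            ids = [f"f{i}" for i in range(n)]
            adj = _adj(counts, ids, [None] * n)
            ours = sum(e.weight for e in span_and_orient(adj).edges)
            G = nx.Graph()
            G.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if counts[i, j] > 0:
                        G.add_edge(i, j, weight=int(counts[i, j]))
            theirs = sum(
                d["weight"] for *_, d in nx.maximum_spanning_edges(G, data=True)
            )
            assert ours == theirs

    def test_fuzzed_instances_respect_dates_and_acyclicity(self, rng):
        """No output edge ever points from a later to an earlier figure."""
        base = datetime.date(2010, 1, 1)
        for trial in range(100):
            n = int(rng.integers(2, 10))
            counts = rng.integers(0, 50, (n, n))
            counts = np.triu(counts, 1)
            counts = counts + counts.T
            dates = [
                None if rng.random() < 0.2 else base + datetime.timedelta(int(rng.integers(0, 3000)))
                for _ in range(n)
            ]
            adj = _adj(counts, [f"f{i}" for i in range(n)], dates)
            g = span_and_orient(adj)
            by_id = {nd.figure_id: nd.date for nd in g.nodes}
            D = nx.DiGraph()
            D.add_nodes_from(by_id)
            for e in g.edges:
                ds, dt = by_id[e.source], by_id[e.target]
                if ds is not None and dt is not None:
                    assert ds <= dt
                D.add_edge(e.source, e.target)
            assert nx.is_directed_acyclic_graph(D)
            assert len(g.edges) <= n - 1

    def test_isolated_figures_stay_as_singletons(self):
        adj = _adj([[0, 0], [0, 0]], ["A", "B"], [None, None])
        g = span_and_orient(adj)
        assert [nd.figure_id for nd in g.nodes] == ["A", "B"]
        assert g.edges == []


class TestGraphIO:
    def test_empty_and_singleton_round_trip(self, tmp_path):
        for g in (ProvenanceGraph(), ProvenanceGraph(nodes=[GraphNode("only")])):
            export_graph(g, tmp_path / "g.json")
            back = import_graph(tmp_path / "g.json")
            assert back.nodes == g.nodes and back.edges == g.edges

    def test_seeded_forest_round_trip(self, tmp_path, rng):
        nodes = [
            GraphNode(f"n{i}", doi=f"10.0/{i}", date=datetime.date(2015, 1, 1 + i))
            for i in range(10)
        ]
        edges = [
            GraphEdge(f"n{i}", f"n{i + 1}", weight=int(rng.integers(1, 99)))
            for i in range(9)
        ]
        g = ProvenanceGraph(nodes=nodes, edges=edges)
        export_graph(g, tmp_path / "g.json")
        back = import_graph(tmp_path / "g.json")
        assert sorted(back.nodes, key=lambda n: n.figure_id) == sorted(
            g.nodes, key=lambda n: n.figure_id
        )
        assert sorted(back.edges, key=lambda e: e.source) == sorted(
            g.edges, key=lambda e: e.source
        )

    def test_malformed_json_reports_line(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"nodes": [,]}')
        with pytest.raises(ValidationError, match="line"):
            import_graph(bad)
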