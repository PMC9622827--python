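"""RootSIFT description, exact inverted-file search and vote ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from conftest import micrograph_figure
from scifig.retrieval import (
    InvertedIndex,
    build_index,
    describe_figure,
    query_rank,
    root_sift,
)
from scifig.types import Box, FigureRecord, RasterImage, ValidationError


class TestRootSift:
    def test_worked_example(self):
        raw = np.zeros(128)
        raw[:3] = [1, 1, 2]
        out = root_sift(raw)
        np.testing.assert_allclose(out[:3], [0.5, 0.5, 0.70711], atol=1e-5)
        assert (out[3:] == 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e3), min_size=128, max_size=128))
    def test_nonzero_inputs_map_to_unit_sphere(self, values):
        raw = np.array(values)
        out = root_sift(raw)
        if raw.sum() > 0:
            assert abs(np.linalg.norm(out) - 1) < 1e-9
        else:
            assert (out == 0).all()

    def test_all_zero_passthrough_and_negative_rejected(self):
        assert (root_sift(np.zeros(128)) == 0).all()
        with pytest.raises(ValidationError):
            root_sift(np.array([-1.0] + [0.0] * 127))


class TestDescribeFigure:
    def test_constant_image_yields_nothing(self):
        fig = FigureRecord(id="c", image=RasterImage(np.full((64, 64), 128, np.uint8), "c"))
        assert describe_figure(fig) == []

    def test_both_views_present_and_capped(self):
        fig = micrograph_figure(1)
        pairs = describe_figure(fig, n_points=50)
        flags = {kp.mirrored for kp, _ in pairs}
        assert flags == {False, True}
        assert len(pairs) <= 100
        assert sum(1 for kp, _ in pairs if not kp.mirrored) <= 50

    def test_keypoints_in_text_regions_discarded(self):
        fig = micrograph_figure(1)
        free = describe_figure(fig, n_points=500)
        fig.text_regions = [Box(0, 0, 128, 64)]
        masked = describe_figure(fig, n_points=500)
        assert len(masked) < len(free)
        for kp, _ in masked:
            if not kp.mirrored:
                assert kp.col >= 64
            else:  # mirrored frame: the text box is mirrored too
                assert kp.col < 64

    def test_deterministic_top_keypoint(self):
        fig = micrograph_figure(2)
        a = describe_figure(fig)[0][0]
        b = describe_figure(fig)[0][0]
        assert (a.row, a.col, a.response) == (b.row, b.col, b.response)


class TestInvertedIndex:
    def test_empty_index(self):
        idx = InvertedIndex()
        assert len(idx) == 0
        d, i = idx.search(np.zeros((1, 128)), 5)
        assert d.shape == (1, 0)

    def test_size_counts_descriptors(self):
        idx = InvertedIndex()
        idx.add_figure("a", [np.zeros(128)] * 7, [False] * 7)
        assert len(idx) == 7

    def test_duplicate_figure_rejected(self):
        idx = InvertedIndex()
        idx.add_figure("a", [np.zeros(128)], [False])
        with pytest.raises(ValidationError):
            idx.add_figure("a", [np.zeros(128)], [False])

    def test_planted_descriptor_is_own_nearest_neighbor(self, rng):
        idx = InvertedIndex()
        vecs = [root_sift(rng.random(128)) for _ in range(20)]
        idx.add_figure("a", vecs, [False] * 20)
        d, i = idx.search(vecs[13][None, :], 1)
        assert i[0, 0] == 13 and d[0, 0] < 1e-12

    def test_exact_search_matches_brute_force(self, rng):
        """k-NN results equal a full distance scan, ties by insertion order."""
        idx = InvertedIndex()
        store = rng.random((500, 128))
        for k in range(5):
            chunk = store[k * 100 : (k + 1) * 100]
            idx.add_figure(f"f{k}", list(chunk), [False] * 100)
        queries = rng.random((40, 128))
        d, i = idx.search(queries, 8)
        brute = cdist(queries, store)
        expect = np.argsort(brute, axis=1, kind="stable")[:, :8]
        assert (i == expect).all()
        np.testing.assert_allclose(d, np.take_along_axis(brute, expect, axis=1))


class TestQueryRank:
    def _benchmark(self, n_base=4, mirrored=False):
        figs = []
        for k in range(n_base):
            base = micrograph_figure(40 + k, f"base{k}")
            dup_px = base.image.pixels[:, ::-1] if mirrored else base.image.pixels
            figs.append(base)
            figs.append(
                FigureRecord(id=f"dup{k}", image=RasterImage(np.ascontiguousarray(dup_px), f"dup{k}"))
            )
        return figs

    @pytest.mark.parametrize("mirrored", [False, True])
    def test_duplicate_ranks_first(self, mirrored):
        figs = self._benchmark(mirrored=mirrored)
        index = build_index(figs, n_points=200)
        for k in range(4):
            rank = query_rank(index, figs[2 * k], k_nn=8)
            assert rank.entries[0][0] == f"dup{k}"

    def test_query_figure_absent_and_votes_sorted(self):
        figs = self._benchmark()
        index = build_index(figs, n_points=200)
        rank = query_rank(index, figs[0], k_nn=8)
        ids = [fid for fid, _ in rank.entries]
        votes = [v for _, v in rank.entries]
        assert figs[0].id not in ids
        assert votes == sorted(votes, reverse=True)
        assert len(rank.entries) <= 10

    def test_vote_conservation(self):
        """Total votes equal (query descriptors) x k_nn when the index is
        deep enough; self entries are skipped without consuming slots."""
        figs = self._benchmark()
        index = build_index(figs, n_points=200)
        query = figs[0]
        n_desc = len(describe_figure(query, n_points=200))
        rank = query_rank(index, query, k_nn=8, rank_cap=100)
        assert sum(v for _, v in rank.entries) == n_desc * 8

    def test_featureless_query_yields_empty_rank(self):
        figs = self._benchmark()
        index = build_index(figs, n_points=200)
        blank = FigureRecord(id="blank", image=RasterImage(np.full((64, 64), 200, np.uint8), "b"))
        assert query_rank(index, blank).entries == []

    def test_empty_index_rejected(self):
        blank = FigureRecord(id="q", image=RasterImage(np.zeros((64, 64), np.uint8), "q"))
        with pytest.raises(ValidationError):
            query_rank(InvertedIndex(), blank)
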