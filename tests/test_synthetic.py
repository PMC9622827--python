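"""Phantom generators: determinism, planted ground truth, analytic oracles."""

from math import pi

import numpy as np
import pytest
from scipy import ndimage

from scifig.metrics import pixel_f1
from scifig.synthetic import (
    compose_figure,
    make_blot_panel,
    make_clone_figure,
    make_color_panel,
    make_micrograph_panel,
    make_reuse_case,
    plant_clone,
)
from scifig.types import Box, RasterImage, ValidationError, as_gray


class TestDeterminism:
    @pytest.mark.parametrize(
        "factory",
        [
            lambda: make_blot_panel(5),
            lambda: make_micrograph_panel(5),
            lambda: make_color_panel(5),
            lambda: compose_figure([make_blot_panel(1, size=(64, 64))], (1, 1), True, 3)[0],
        ],
    )
    def test_regeneration_is_bit_identical(self, factory):
        assert (factory().pixels == factory().pixels).all()

    def test_reuse_case_bit_identical(self):
        a = make_reuse_case(3, 1, seed=4)
        b = make_reuse_case(3, 1, seed=4)
        for fa, fb in zip(a.figures, b.figures):
            assert fa.id == fb.id and (fa.image.pixels == fb.image.pixels).all()
        assert a.truth_graph.edges == b.truth_graph.edges


class TestBlotPanel:
    def test_no_lanes_is_blank_noise(self):
        panel = make_blot_panel(0, lanes=0, bands_per_lane=0)
        assert (np.abs(panel.pixels.astype(int) - 230) < 40).all()

    def test_dark_mass_matches_analytic_band_area(self):
        """Pixels below 128 weigh within 20% of the analytic prediction.

        The blur is a symmetric Gaussian, so across each band edge the
        intensity profile is core + (bg - core) * Phi(x / sigma); the
        128-level contour therefore sits at a predictable offset delta
        inside the drawn ellipse, and the expected dark mass is the sum
        of the eroded ellipse areas pi (a - delta)(b - delta).
        """
        from scipy.stats import norm

        panel, geom = make_blot_panel(1, return_geometry=True)
        bg = geom["background"]
        sigma = 1.5
        predicted = 0.0
        for _, _, a, b, depth in geom["bands"]:
            core = bg - depth
            delta = -sigma * norm.ppf((128 - core) / (bg - core))
            predicted += pi * max(a - delta, 0) * max(b - delta, 0)
        measured = int((panel.pixels < 128).sum())
        assert 0.8 * predicted <= measured <= 1.2 * predicted

    def test_undersized_rejected(self):
        with pytest.raises(ValidationError):
            make_blot_panel(0, size=(32, 64))


class TestMicrographPanel:
    def test_no_cells_is_background_only(self):
        panel = make_micrograph_panel(2, n_cells=0)
        assert (panel.pixels < 190).all()

    def test_blob_count_recovered_by_labeling(self):
        """Sparse planted cells are countable by threshold + labeling."""
        panel = make_micrograph_panel(3, n_cells=6, size=(160, 160))
        bright = panel.pixels > 170
        bright = ndimage.binary_opening(bright, np.ones((3, 3)))
        _, n = ndimage.label(bright)
        assert n == 6


class TestComposeFigure:
    def test_single_panel_box(self):
        p = make_blot_panel(0, size=(64, 64))
        fig, boxes, _ = compose_figure([p], (1, 1))
        assert len(boxes) == 1
        assert (fig.pixels[boxes[0].slices()] == p.pixels).all()

    def test_2x2_grid_boxes_disjoint_and_content_preserved(self):
        panels = [make_blot_panel(i, size=(64, 64)) for i in range(4)]
        fig, boxes, _ = compose_figure(panels, (2, 2))
        assert len(boxes) == 4
        for i, (b, p) in enumerate(zip(boxes, panels)):
            assert (fig.pixels[b.slices()] == p.pixels).all()
            for other in boxes[i + 1 :]:
                assert not b.intersects(other)

    def test_too_many_panels_rejected(self):
        panels = [make_blot_panel(i, size=(64, 64)) for i in range(3)]
        with pytest.raises(ValidationError):
            compose_figure(panels, (1, 2))


class TestPlantClone:
    def test_rigid_copy_is_exact_and_mask_double_area(self):
        fig = make_micrograph_panel(4, size=(128, 128))
        src = Box(10, 10, 42, 42)
        out, mask = plant_clone(fig, src, (70, 70), "none")
        assert (out.pixels[70:102, 70:102] == fig.pixels[src.slices()]).all()
        assert mask.sum() == 2 * src.area

    def test_mirror_h_flips_source(self):
        fig = make_micrograph_panel(5, size=(128, 128))
        src = Box(10, 10, 42, 42)
        out, _ = plant_clone(fig, src, (70, 70), "mirror_h")
        assert (out.pixels[70:102, 70:102] == fig.pixels[src.slices()][:, ::-1]).all()

    def test_overlap_and_out_of_bounds_rejected(self):
        fig = make_micrograph_panel(6, size=(96, 96))
        src = Box(10, 10, 42, 42)
        with pytest.raises(ValidationError):
            plant_clone(fig, src, (30, 30), "none")  # overlaps src
        with pytest.raises(ValidationError):
            plant_clone(fig, src, (80, 80), "none")  # runs off the frame

    def test_clone_figures_have_valid_truth(self):
        for kind in ("rigid", "mirror", "color", "pristine"):
            rec, mask = make_clone_figure(9, kind)
            assert mask.shape == rec.image.shape
            if kind == "pristine":
                assert not mask.any()
            else:
                assert mask.any()


class TestReuseCase:
    def test_minimal_case_one_dated_edge(self):
        case = make_reuse_case(2, 1, seed=0)
        (edge,) = case.truth_graph.edges
        dates = {n.figure_id: n.date for n in case.truth_graph.nodes}
        assert dates[edge.source] < dates[edge.target]

    def test_every_truth_edge_respects_dates(self):
        case = make_reuse_case(6, 1, seed=2)
        dates = {n.figure_id: n.date for n in case.truth_graph.nodes}
        for e in case.truth_graph.edges:
            assert dates[e.source] < dates[e.target]

    def test_requires_two_papers(self):
        with pytest.raises(ValidationError):
            make_reuse_case(1, 1, seed=0)
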