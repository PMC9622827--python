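"""Shared fixtures: small seeded images and figure records.

All fixtures are generated programmatically; nothing is read from disk
except what a test itself writes into ``tmp_path``.
"""

import numpy as np
import pytest

from scifig.types import FigureRecord, RasterImage


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def noise_image(rng):
    """128x128 uniform-noise grayscale image (rich in texture)."""
    return RasterImage(rng.integers(0, 256, (128, 128), dtype=np.uint8), "noise")


@pytest.fixture()
def noise_figure(noise_image):
    return FigureRecord(id="noise", image=noise_image)


def micrograph_figure(seed: int, fid: str | None = None) -> FigureRecord:
    """A textured micrograph-like figure for keypoint-based tests."""
    from scifig.synthetic import make_micrograph_panel

    panel = make_micrograph_panel(seed, n_cells=12, size=(128, 128))
    return FigureRecord(id=fid or f"micro-{seed}", image=panel)
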