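import numpy as np
import pytest

from ruffscore.board import load_layout
from ruffscore.ingest import CellInk, PageImage, segment_red
from ruffscore.recognize import RecognitionConfig
from ruffscore.render import render_cell, zero_noise


@pytest.fixture(scope="session")
def layout():
    return load_layout()


@pytest.fixture(scope="session")
def config(layout):
    return RecognitionConfig(dot_radius_px=layout.dot_radius_px)


@pytest.fixture(scope="session")
def cell_factory(layout):
    """Render a single cell and return it as ingested CellInk.

    ``via='color'`` runs the rendered image through the HSV red
    segmentation (the real ingestion path); ``via='alpha'`` uses the
    renderer's own ink-coverage mask, bypassing color handling.
    """

    def make(design, part=1, noise=None, rng=None, violation=False, via="color"):
        noise = noise or zero_noise()
        img, alpha, violating = render_cell(design, layout, part, noise,
                                            rng=rng, violation=violation)
        if via == "color":
            page = PageImage(raster=img, dpi=layout.dpi, part_number=part)
            mask = segment_red(page)
        else:
            mask = alpha >= 0.5
        cell = CellInk(cell_index=0, part_number=part, red_mask=mask,
                       dot_centers_px=layout.dot_centers_cell(part))
        return cell, violating

    return make
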