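"""End-to-end convenience: pages in, protocol scores out."""

from __future__ import annotations

from dataclasses import dataclass

from .board import BoardLayout
from .ingest import PageImage, RedWindow, ingest_page
from .recognize import RecognitionConfig, RecognizedCell, recognize_cell
from .render import RenderedProtocol
from .scoring import ProtocolScore, score_protocol


@dataclass
class ProtocolResult:
    score: ProtocolScore
    cells_by_part: dict[int, list[RecognizedCell]]


def recognize_page(
    page: PageImage,
    layout: BoardLayout,
    config: RecognitionConfig | None = None,
    window: RedWindow | None = None,
) -> list[RecognizedCell]:
    """Ingest and recognize all 35 cells of one scanned page."""
    config = (config or RecognitionConfig()).scaled(layout.dpi)
    partition = ingest_page(page, layout, window)
    return [recognize_cell(cell, config) for cell in partition.cells]


def score_pages(
    pages: dict[int, PageImage],
    layout: BoardLayout,
    config: RecognitionConfig | None = None,
    window: RedWindow | None = None,
) -> ProtocolResult:
    """Score a full protocol from its five part pages."""
    cells = {part: recognize_page(page, layout, config, window)
             for part, page in pages.items()}
    return ProtocolResult(score=score_protocol(cells), cells_by_part=cells)


def score_rendered(
    rendered: RenderedProtocol,
    layout: BoardLayout,
    config: RecognitionConfig | None = None,
    window: RedWindow | None = None,
) -> ProtocolResult:
    """Run the full scan pipeline on an in-memory synthetic render."""
    pages = {part: PageImage(raster=img, dpi=layout.dpi, part_number=part)
             for part, img in rendered.pages.items()}
    return score_pages(pages, layout, config, window)
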