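"""Scan ingestion: load pages, register the board, extract respondent ink.

A scanned protocol page contains printed black geometry (dots, distractor
diamonds or lines, at known layout positions) and the respondent's red
strokes.  This module (1) segments the red ink in HSV space, (2) locates
the printed dots and fits a similarity transform aligning the configured
layout with the actual scan, and (3) partitions the red ink into 35
per-cell masks expressed in the layout's cell-local frame, ready for
connection recognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.spatial import cKDTree
from skimage import measure
from skimage.color import rgb2hsv
from skimage.transform import SimilarityTransform

from .board import N_CELLS, N_DOTS, BoardLayout


class RegistrationError(RuntimeError):
    """The printed dot grid could not be located on the page."""


class UnsupportedInputError(ValueError):
    """The raster is not a color image."""


@dataclass
class PageImage:
    """One scanned protocol page: (H, W, 3) uint8 color raster."""

    raster: np.ndarray
    dpi: float
    part_number: int

    def __post_init__(self) -> None:
        if not 1 <= self.part_number <= 5:
            raise ValueError("part_number must be 1..5")
        if self.raster.ndim == 3 and self.raster.shape[2] == 4:
            self.raster = self.raster[..., :3]

    @classmethod
    def from_file(cls, path, dpi: float, part_number: int) -> "PageImage":
        arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(raster=arr, dpi=dpi, part_number=part_number)


@dataclass(frozen=True)
class RedWindow:
    """HSV window defining "respondent red".

    Hue is degrees on the color wheel; the window is symmetric around 0
    (pure red) so it wraps across 360.  Saturation/value minima exclude
    white paper and black print.
    """

    hue_halfwidth_deg: float = 20.0
    saturation_min: float = 0.35
    value_min: float = 0.25


def segment_red(page: PageImage, window: RedWindow | None = None) -> np.ndarray:
    """Boolean mask of red-ink pixels on the page.

    Black print and white paper fall outside the window: black fails the
    value floor, paper fails the saturation floor.
    """
    window = window or RedWindow()
    if page.raster.ndim != 3 or page.raster.shape[2] != 3:
        raise UnsupportedInputError("segment_red requires an RGB raster")
    rast = page.raster
    # Cheap integer prefilter: a strict superset of any red-centred window
    # (max channel is R, value and saturation floors), so the exact HSV
    # test below only runs on candidate pixels, not the whole page.
    r = rast[..., 0].astype(np.int16)
    g = rast[..., 1].astype(np.int16)
    b = rast[..., 2].astype(np.int16)
    candidate = (
        (r >= int(window.value_min * 255))
        & (r >= g) & (r >= b)
        & (np.minimum(g, b) * 100 <= r * int(100 * (1 - window.saturation_min) + 1))
    )
    mask = np.zeros(rast.shape[:2], dtype=bool)
    ys, xs = np.nonzero(candidate)
    if ys.size == 0:
        return mask
    hsv = rgb2hsv(rast[ys, xs].reshape(-1, 1, 3)).reshape(-1, 3)
    hue_deg = hsv[:, 0] * 360.0
    dist = np.minimum(hue_deg, 360.0 - hue_deg)  # angular distance to red
    ok = (
        (dist <= window.hue_halfwidth_deg)
        & (hsv[:, 1] >= window.saturation_min)
        & (hsv[:, 2] >= window.value_min)
    )
    mask[ys[ok], xs[ok]] = True
    return mask


@dataclass
class Registration:
    """Similarity transform mapping layout coordinates to the scanned page."""

    transform: SimilarityTransform
    dot_centers_page: np.ndarray  # (35, 5, 2) xy, layout dots mapped to the page
    matched_fraction: float
    mean_residual_px: float
    max_residual_px: float


def detect_dots(page: PageImage, layout: BoardLayout,
                darkness_max: int = 110) -> np.ndarray:
    """Centroids (xy) of printed-dot-sized black blobs on the page.

    Distractors are rejected by shape: part-2 diamonds are smaller than
    dots (area floor), part-3 line segments are elongated (eccentricity
    ceiling).  Red ink is not dark and never enters the mask.
    """
    dark = page.raster.max(axis=2) < darkness_max
    labels = measure.label(dark, connectivity=2)
    dot_area = np.pi * layout.dot_radius_px ** 2
    centers = []
    for region in measure.regionprops(labels):
        if not 0.35 * dot_area <= region.area <= 2.5 * dot_area:
            continue
        if region.eccentricity > 0.92:
            continue
        cy, cx = region.centroid
        centers.append((cx, cy))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(src, dst)
        if not tf:
            raise RegistrationError("similarity transform estimation failed")
        return tf
    tf = SimilarityTransform()
    if not tf.estimate(src, dst):
        raise RegistrationError("similarity transform estimation failed")
    return tf


def register_layout(
    page: PageImage,
    layout: BoardLayout,
    min_match_fraction: float = 0.8,
    max_mean_residual_px: float = 2.0,
    n_iterations: int = 3,
) -> Registration:
    """Fit a similarity transform (translation, uniform scale, small
    rotation) from layout coordinates to the scanned page.

    Matches each expected dot center to the nearest detected black blob
    and refines by least squares.  Raises :class:`RegistrationError` when
    fewer than ``min_match_fraction`` of the 175 dots are found or the
    mean residual stays above ``max_mean_residual_px``.
    """
    expected = layout.dot_centers_page(page.part_number).reshape(-1, 2)
    detected = detect_dots(page, layout)
    if len(detected) < min_match_fraction * len(expected):
        raise RegistrationError(
            f"only {len(detected)} dot-like blobs found, "
            f"expected about {len(expected)}")
    tree = cKDTree(detected)
    transform = SimilarityTransform()
    tol = 0.45 * min(layout.cell_width, layout.cell_height)
    projected = expected
    matched = None
    for _ in range(n_iterations):
        dist, nearest = tree.query(projected)
        matched = dist < tol
        if matched.sum() < min_match_fraction * len(expected):
            raise RegistrationError(
                f"matched only {int(matched.sum())}/{len(expected)} dots")
        transform = _estimate_similarity(expected[matched],
                                         detected[nearest[matched]])
        projected = transform(expected)
        tol = max(6.0 * layout.dpi / 300.0, 0.1 * min(layout.cell_width,
                                                      layout.cell_height))
    dist, nearest = tree.query(projected)
    matched = dist < tol
    residuals = dist[matched]
    if residuals.size == 0 or residuals.mean() > max_mean_residual_px:
        raise RegistrationError("registration residuals too large")
    return Registration(
        transform=transform,
        dot_centers_page=transform(expected).reshape(N_CELLS, N_DOTS, 2),
        matched_fraction=float(matched.mean()),
        mean_residual_px=float(residuals.mean()),
        max_residual_px=float(residuals.max()),
    )


@dataclass
class CellInk:
    """Respondent ink of one cell, in cell-local layout coordinates.

    ``red_mask`` is a (cell_height, cell_width) boolean raster;
    ``dot_centers_px`` the five dot centers in the same frame.
    ``n_red_pixels`` counts the page pixels assigned to this cell (several
    may round onto one mask bit under rotation).
    """

    cell_index: int
    part_number: int
    red_mask: np.ndarray
    dot_centers_px: np.ndarray
    n_red_pixels: int = 0

    def __post_init__(self) -> None:
        if self.n_red_pixels == 0:
            self.n_red_pixels = int(self.red_mask.sum())


@dataclass
class CellPartition:
    cells: list[CellInk]
    n_dropped_pixels: int


def crop_cells(
    page: PageImage,
    red_mask: np.ndarray,
    registration: Registration,
    layout: BoardLayout,
) -> CellPartition:
    """Partition red-ink pixels into the 35 cells of the registered grid.

    Pixels are mapped back into the layout frame through the inverse
    similarity transform; those landing outside every cell box are
    counted as dropped.
    """
    h = int(round(layout.cell_height))
    w = int(round(layout.cell_width))
    ys, xs = np.nonzero(red_mask)
    if ys.size:
        pts = registration.transform.inverse(np.column_stack([xs, ys]))
    else:
        pts = np.empty((0, 2))
    col = np.floor((pts[:, 0] - layout.grid_x0) / layout.cell_width).astype(int)
    row = np.floor((pts[:, 1] - layout.grid_y0) / layout.cell_height).astype(int)
    inside = (0 <= col) & (col < layout.n_cols) & (0 <= row) & (row < layout.n_rows)
    dropped = int((~inside).sum())
    cells = []
    local_centers = layout.dot_centers_cell(page.part_number)
    idx_all = row[inside] * layout.n_cols + col[inside]
    lx = pts[inside, 0] - (layout.grid_x0 + col[inside] * layout.cell_width)
    ly = pts[inside, 1] - (layout.grid_y0 + row[inside] * layout.cell_height)
    ix = np.clip(np.round(lx).astype(int), 0, w - 1)
    iy = np.clip(np.round(ly).astype(int), 0, h - 1)
    for cell_idx in range(N_CELLS):
        sel = idx_all == cell_idx
        mask = np.zeros((h, w), dtype=bool)
        mask[iy[sel], ix[sel]] = True
        cells.append(CellInk(
            cell_index=cell_idx,
            part_number=page.part_number,
            red_mask=mask,
            dot_centers_px=local_centers.copy(),
            n_red_pixels=int(sel.sum()),
        ))
    return CellPartition(cells=cells, n_dropped_pixels=dropped)


def ingest_page(
    page: PageImage,
    layout: BoardLayout,
    window: RedWindow | None = None,
) -> CellPartition:
    """Full ingestion of one page: segment red ink, register, crop cells."""
    red = segment_red(page, window)
    reg = register_layout(page, layout)
    return crop_cells(page, red, reg, layout)
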