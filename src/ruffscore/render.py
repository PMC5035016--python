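"""Synthetic RFFT protocol renderer.

Real validation data — color scans of respondent-completed protocol
sheets — are clinical records and cannot ship with the package.  This
module renders *synthetic* scans from a known design script instead:
black five-dot patterns (plus the part-specific printed distractors) and
red respondent strokes with a configurable hand-drawing noise model.
Because the script is known, every render comes with machine-readable
ground truth, so the whole recognition pipeline can be tested round-trip.

The noise model covers the failure modes seen in real protocols: curved
or jittered lines, strokes that stop short of the dots, and the
"crossed the dots" violation mode in which strokes overshoot straight
through their endpoint dots.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .board import (
    MAX_DESIGN_ID,
    N_CELLS,
    BoardLayout,
    Connection,
    design_from_id,
    design_id,
)

#: Saturated scanner-red of the rendered respondent ink (RGB).
RED_INK = np.array([205.0, 30.0, 40.0])
BLACK = np.array([0.0, 0.0, 0.0])


@dataclass(frozen=True)
class StrokeNoiseModel:
    """Hand-drawing noise applied to each rendered stroke.

    All distances are pixels at the layout's dpi.  ``jitter_sd_px``
    displaces stroke endpoints (Gaussian, isotropic);
    ``curvature_amplitude_px`` bows the stroke into a quadratic arc with
    a uniform random bow in ``[-amp, +amp]``; ``endpoint_shortfall_px``
    stops strokes short of the dot centers; ``overshoot_px`` is how far a
    *violating* stroke extends straight through each endpoint dot.  A
    stroke violates when its cell is scripted as violating or with
    ``violation_probability`` otherwise.  Identical seeds give
    bit-identical renders.
    """

    jitter_sd_px: float = 0.0
    curvature_amplitude_px: float = 0.0
    stroke_width_px: float = 3.0
    endpoint_shortfall_px: float = 0.0
    overshoot_px: float = 24.0
    violation_probability: float = 0.0
    color_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jitter_sd_px", "curvature_amplitude_px", "stroke_width_px",
                     "endpoint_shortfall_px", "overshoot_px", "color_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.violation_probability <= 1.0:
            raise ValueError("violation_probability must be in [0, 1]")

    def with_seed(self, seed: int) -> "StrokeNoiseModel":
        return replace(self, seed=seed)


def zero_noise(seed: int = 0) -> StrokeNoiseModel:
    """Perfectly compliant straight strokes ending exactly on dot centers."""
    return StrokeNoiseModel(seed=seed)


def moderate_noise(seed: int = 0) -> StrokeNoiseModel:
    """Plausible hand-drawing noise at 300 dpi: 1 px endpoint jitter,
    up to 2 px bow, 1 px shortfall, light scanner color noise."""
    return StrokeNoiseModel(
        jitter_sd_px=1.0,
        curvature_amplitude_px=2.0,
        endpoint_shortfall_px=1.0,
        color_noise_sd=6.0,
        seed=seed,
    )


class CellScript(NamedTuple):
    """One scripted cell: a design ID (0 = blank) and whether the cell is
    drawn in violation mode (all its strokes cross through the dots)."""

    design: int
    violation: bool = False


@dataclass
class ProtocolScript:
    """Ordered designs for the five parts of one protocol.

    Cells are filled in row-major order starting at cell 0, mirroring how
    respondents work through a sheet; at most 35 entries per part.
    """

    parts: dict[int, list[CellScript]]

    def __post_init__(self) -> None:
        if sorted(self.parts) != [1, 2, 3, 4, 5]:
            raise ValueError("script must cover parts 1..5")
        for part, cells in self.parts.items():
            if len(cells) > N_CELLS:
                raise ValueError(f"part {part}: more than {N_CELLS} cells")
            self.parts[part] = [CellScript(*c) for c in cells]
            for c in self.parts[part]:
                if not 0 <= c.design <= MAX_DESIGN_ID:
                    raise ValueError(f"design ID {c.design} out of range")

    def effective_designs(self, exclude_violations: bool = True) -> dict[int, list[int]]:
        """Design IDs as the recognizer should report them.

        Violating strokes are excluded from true connections, so a
        violation-mode cell scores as design 0 unless violations are
        configured to count as designs.
        """
        out: dict[int, list[int]] = {}
        for part, cells in self.parts.items():
            out[part] = [
                0 if (c.violation and exclude_violations) else c.design
                for c in cells
            ]
        return out

    def violation_counts(self) -> dict[int, list[int]]:
        """Per-cell count of violating strokes (one per drawn connection)."""
        return {
            part: [bin(c.design).count("1") if c.violation else 0 for c in cells]
            for part, cells in self.parts.items()
        }

    def to_jsonable(self) -> dict:
        return {
            str(part): [[c.design, bool(c.violation)] for c in cells]
            for part, cells in self.parts.items()
        }

    @classmethod
    def from_jsonable(cls, raw: dict) -> "ProtocolScript":
        return cls({int(p): [CellScript(int(d), bool(v)) for d, v in cells]
                    for p, cells in raw.items()})


def random_script(
    n_filled_cells_per_part: int,
    perseveration_rate: float,
    seed: int | np.random.Generator = 0,
    violation_rate: float = 0.0,
) -> ProtocolScript:
    """Draw a random protocol script.

    Fresh designs are sampled *without replacement* within a part
    (respondents strive for novelty), so with ``perseveration_rate`` 0
    every filled cell is a unique design.  After the first cell of a
    part, each subsequent cell instead repeats a uniformly chosen earlier
    design with probability ``perseveration_rate``.  ``violation_rate``
    marks whole cells as drawn in violation mode.
    """
    if not 0 <= n_filled_cells_per_part <= N_CELLS:
        raise ValueError("n_filled_cells_per_part must be in 0..35")
    if not 0.0 <= perseveration_rate <= 1.0:
        raise ValueError("perseveration_rate must be in [0, 1]")
    if not 0.0 <= violation_rate <= 1.0:
        raise ValueError("violation_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: dict[int, list[CellScript]] = {}
    for part in range(1, 6):
        unused = list(range(1, MAX_DESIGN_ID + 1))
        drawn: list[int] = []
        cells: list[CellScript] = []
        for i in range(n_filled_cells_per_part):
            if i > 0 and rng.random() < perseveration_rate:
                design = drawn[rng.integers(len(drawn))]
            else:
                j = rng.integers(len(unused))
                design = unused.pop(j)
            drawn.append(design)
            cells.append(CellScript(design, bool(rng.random() < violation_rate)))
        parts[part] = cells
    return ProtocolScript(parts)


@dataclass
class RenderedProtocol:
    """Five rendered page images plus the ground truth they encode.

    ``pages`` maps part number to an (H, W, 3) uint8 raster.
    ``stroke_alpha`` holds the renderer's own per-page ink coverage
    (in-memory only, for pixel-level tests; not serialized).
    """

    script: ProtocolScript
    pages: dict[int, np.ndarray]
    ground_truth: dict
    stroke_alpha: dict[int, np.ndarray] = field(default_factory=dict)

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=1)


def _stamp_capsule(canvas, alpha_acc, p0, p1, width, color) -> None:
    """Composite a round-capped thick segment onto ``canvas`` with a soft
    (~1 px) anti-aliased edge; record coverage in ``alpha_acc`` if given."""
    h, w = canvas.shape[:2]
    half = width / 2.0
    pad = int(np.ceil(half)) + 1
    x0 = max(int(np.floor(min(p0[0], p1[0]))) - pad, 0)
    x1 = min(int(np.ceil(max(p0[0], p1[0]))) + pad, w - 1)
    y0 = max(int(np.floor(min(p0[1], p1[1]))) - pad, 0)
    y1 = min(int(np.ceil(max(p0[1], p1[1]))) + pad, h - 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1, dtype=np.float32)
    ys = np.arange(y0, y1 + 1, dtype=np.float32)
    X, Y = np.meshgrid(xs, ys)
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    lsq = dx * dx + dy * dy
    if lsq == 0:
        cx = np.full_like(X, p0[0])
        cy = np.full_like(Y, p0[1])
    else:
        t = np.clip(((X - p0[0]) * dx + (Y - p0[1]) * dy) / lsq, 0.0, 1.0)
        cx = p0[0] + t * dx
        cy = p0[1] + t * dy
    d = np.hypot(X - cx, Y - cy)
    alpha = np.clip(half + 0.5 - d, 0.0, 1.0)
    if not alpha.any():
        return
    region = canvas[y0:y1 + 1, x0:x1 + 1].astype(np.float32)
    a3 = alpha[..., None]
    canvas[y0:y1 + 1, x0:x1 + 1] = (
        region * (1.0 - a3) + np.asarray(color, np.float32) * a3
    ).round().astype(np.uint8)
    if alpha_acc is not None:
        np.maximum(alpha_acc[y0:y1 + 1, x0:x1 + 1], alpha, out=alpha_acc[y0:y1 + 1, x0:x1 + 1])


def _stamp_diamond(canvas, center, half_diag) -> None:
    h, w = canvas.shape[:2]
    pad = int(np.ceil(half_diag)) + 1
    x0 = max(int(center[0]) - pad, 0)
    x1 = min(int(center[0]) + pad, w - 1)
    y0 = max(int(center[1]) - pad, 0)
    y1 = min(int(center[1]) + pad, h - 1)
    xs = np.arange(x0, x1 + 1, dtype=np.float32)
    ys = np.arange(y0, y1 + 1, dtype=np.float32)
    X, Y = np.meshgrid(xs, ys)
    l1 = np.abs(X - center[0]) + np.abs(Y - center[1])
    alpha = np.clip(half_diag + 0.5 - l1, 0.0, 1.0)
    region = canvas[y0:y1 + 1, x0:x1 + 1].astype(np.float32)
    a3 = alpha[..., None]
    canvas[y0:y1 + 1, x0:x1 + 1] = (region * (1.0 - a3)).round().astype(np.uint8)


def _bezier_points(p0, c, p1, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t ** 2 * p1


def _draw_stroke(canvas, alpha_acc, a, b, noise: StrokeNoiseModel,
                 rng: np.random.Generator, violating: bool) -> None:
    """One respondent stroke between dot centers ``a`` and ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u = b - a
    length = float(np.hypot(*u))
    u = u / length
    if violating:
        p0 = a - u * noise.overshoot_px
        p1 = b + u * noise.overshoot_px
    else:
        p0 = a + u * noise.endpoint_shortfall_px
        p1 = b - u * noise.endpoint_shortfall_px
    if noise.jitter_sd_px > 0:
        p0 = p0 + rng.normal(0.0, noise.jitter_sd_px, 2)
        p1 = p1 + rng.normal(0.0, noise.jitter_sd_px, 2)
    bow = 0.0
    if noise.curvature_amplitude_px > 0:
        bow = float(rng.uniform(-noise.curvature_amplitude_px, noise.curvature_amplitude_px))
    if bow == 0.0:
        _stamp_capsule(canvas, alpha_acc, p0, p1, noise.stroke_width_px, RED_INK)
        return
    mid = (p0 + p1) / 2.0
    perp = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    perp = perp / np.hypot(*perp)
    control = mid + 2.0 * bow * perp  # quadratic Bezier reaches `bow` at t=0.5
    n_seg = max(4, int(length / 16))
    pts = _bezier_points(p0, control, p1, n_seg)
    for i in range(n_seg):
        _stamp_capsule(canvas, alpha_acc, pts[i], pts[i + 1], noise.stroke_width_px, RED_INK)


def _draw_cell_print(canvas, origin, layout: BoardLayout, part: int) -> None:
    """Printed (black) geometry of one cell: dots and distractors."""
    dl = layout.parts[part]
    centers = layout.dot_centers_cell(part) + origin
    for cx, cy in centers:
        _stamp_capsule(canvas, None, (cx, cy), (cx, cy),
                       2 * layout.dot_radius_px, BLACK)
    scale = np.array([layout.cell_width, layout.cell_height])
    if dl.distractor_kind == "diamonds":
        for pos in dl.distractor_positions:
            c = np.asarray(pos) * scale + origin
            _stamp_diamond(canvas, c, layout.diamond_half_diag_px)
    elif dl.distractor_kind == "lines":
        for x1, y1, x2, y2 in dl.distractor_positions:
            p = np.array([x1, y1]) * scale + origin
            q = np.array([x2, y2]) * scale + origin
            _stamp_capsule(canvas, None, p, q, layout.line_width_px, BLACK)


def render_cell(
    design: int,
    layout: BoardLayout,
    part: int,
    noise: StrokeNoiseModel | None = None,
    rng: np.random.Generator | None = None,
    violation: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[Connection]]:
    """Render a single cell on its own canvas.

    Returns ``(image, stroke_alpha, violating_connections)`` with the
    image sized to one cell box and dot centers at
    ``layout.dot_centers_cell(part)``.
    """
    noise = noise or zero_noise()
    rng = rng or np.random.default_rng(noise.seed)
    h = int(round(layout.cell_height))
    w = int(round(layout.cell_width))
    canvas = np.full((h, w, 3), 255, dtype=np.uint8)
    alpha = np.zeros((h, w), dtype=np.float32)
    _draw_cell_print(canvas, np.zeros(2), layout, part)
    centers = layout.dot_centers_cell(part)
    violating: list[Connection] = []
    for conn in sorted(design_from_id(design), key=lambda c: c.canonical_index):
        is_violating = violation or bool(rng.random() < noise.violation_probability)
        if is_violating:
            violating.append(conn)
        _draw_stroke(canvas, alpha, centers[conn.dot_a], centers[conn.dot_b],
                     noise, rng, is_violating)
    _apply_color_noise(canvas, alpha, noise, rng)
    return canvas, alpha, violating


def _apply_color_noise(canvas, alpha, noise: StrokeNoiseModel,
                       rng: np.random.Generator) -> None:
    if noise.color_noise_sd <= 0:
        return
    ys, xs = np.nonzero(alpha > 0)
    if ys.size == 0:
        return
    jitter = rng.normal(0.0, noise.color_noise_sd, (ys.size, 3))
    vals = canvas[ys, xs].astype(np.float32) + jitter
    canvas[ys, xs] = np.clip(vals, 0, 255).round().astype(np.uint8)


def render_protocol(
    script: ProtocolScript,
    layout: BoardLayout,
    noise: StrokeNoiseModel | None = None,
) -> RenderedProtocol:
    """Render all five pages of a protocol plus ground truth.

    Deterministic given ``noise.seed``: the same script, layout and noise
    model always produce bit-identical pages.
    """
    noise = noise or zero_noise()
    rng = np.random.default_rng(noise.seed)
    pages: dict[int, np.ndarray] = {}
    alphas: dict[int, np.ndarray] = {}
    gt_parts: dict[str, list] = {}
    for part in range(1, 6):
        canvas = np.full((layout.page_height_px, layout.page_width_px, 3), 255,
                         dtype=np.uint8)
        alpha = np.zeros(canvas.shape[:2], dtype=np.float32)
        centers_all = layout.dot_centers_page(part)
        for idx in range(N_CELLS):
            x0, y0, _, _ = layout.cell_box(*layout.cell_rowcol(idx))
            _draw_cell_print(canvas, np.array([x0, y0]), layout, part)
        gt_cells = []
        for idx, cell in enumerate(script.parts[part]):
            centers = centers_all[idx]
            violating: list[Connection] = []
            for conn in sorted(design_from_id(cell.design),
                               key=lambda c: c.canonical_index):
                is_violating = cell.violation or bool(
                    rng.random() < noise.violation_probability)
                if is_violating:
                    violating.append(conn)
                _draw_stroke(canvas, alpha, centers[conn.dot_a],
                             centers[conn.dot_b], noise, rng, is_violating)
            eff = design_id(set(design_from_id(cell.design)) - set(violating))
            gt_cells.append({
                "cell": idx,
                "design": cell.design,
                "connections": sorted((c.dot_a, c.dot_b)
                                      for c in design_from_id(cell.design)),
                "violating_connections": sorted((c.dot_a, c.dot_b)
                                                for c in violating),
                "n_violations": len(violating),
                "effective_design": eff,
            })
        _apply_color_noise(canvas, alpha, noise, rng)
        pages[part] = canvas
        alphas[part] = alpha
        gt_parts[str(part)] = gt_cells
    ground_truth = {
        "script": script.to_jsonable(),
        "noise": asdict(noise),
        "parts": gt_parts,
    }
    return RenderedProtocol(script=script, pages=pages, ground_truth=ground_truth,
                            stroke_alpha=alphas)


def iter_protocols(
    n_protocols: int,
    layout: BoardLayout,
    noise: StrokeNoiseModel,
    n_filled_cells_per_part: int = 16,
    perseveration_rate: float = 0.12,
    violation_rate: float = 0.0,
    seed: int = 0,
) -> Iterator[RenderedProtocol]:
    """Stream independent random protocols (scripts and renders) from one seed."""
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_protocols):
        sub = child.generate_state(2)
        script = random_script(n_filled_cells_per_part, perseveration_rate,
                               seed=int(sub[0] % (2 ** 31)),
                               violation_rate=violation_rate)
        yield render_protocol(script, layout,
                              noise.with_seed(int(sub[1] % (2 ** 31))))
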