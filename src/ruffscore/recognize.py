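"""Connection recognition: from a cell's red ink to its design ID.

The recognizer runs five tasks on each cell, mirroring how a human rater
reads a drawing:

1. *Active dots* — dots touched by red ink.
2. *Candidate connections* — every dot pair among the active dots.
3. *Pixel assignment* — each red pixel is attributed to the nearest
   candidate segment within a corridor, exclusively.
4. *Line compatibility* — a candidate is kept only if its pixels cover
   enough of the segment without large gaps, i.e. they actually form the
   claimed line.
5. *False-positive rejection* — a long candidate that merely shadows two
   accepted shorter, nearly collinear candidates through an interior
   active dot is removed unless it has independent pixel support.

Separately, strokes that overshoot straight through their endpoint dots
are counted as procedure violations ("crossed the dots"); by default a
violating stroke yields no true connection.

All thresholds live in :class:`RecognitionConfig` and scale linearly with
resolution relative to the 300 dpi reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .board import Connection, design_id, enumerate_connections
from .ingest import CellInk


@dataclass(frozen=True)
class RecognitionConfig:
    """Thresholds of the five-task recognizer (pixels at 300 dpi).

    ``activation_radius_px`` and ``corridor_halfwidth_px`` default to the
    dot radius plus a small allowance, tolerating strokes that stop just
    short of a dot while excluding grazing ink.  ``coverage_threshold``
    and ``max_gap_fraction`` encode how much of a candidate segment must
    be inked for the pixels to count as a line — loose enough for curved,
    hasty strokes, strict enough to reject partial marks.
    """

    dot_radius_px: float = 6.0
    activation_margin_px: float = 4.0
    min_active_pixels: int = 3
    corridor_margin_px: float = 3.0
    coverage_threshold: float = 0.75
    max_gap_fraction: float = 0.20
    overshoot_threshold_px: float = 10.0
    min_independent_support_px: int = 10
    count_violations_as_designs: bool = False
    dpi: float = 300.0

    @property
    def activation_radius_px(self) -> float:
        return self.dot_radius_px + self.activation_margin_px

    @property
    def corridor_halfwidth_px(self) -> float:
        return self.dot_radius_px + self.corridor_margin_px

    def scaled(self, dpi: float) -> "RecognitionConfig":
        """Same physical thresholds at another scan resolution."""
        f = dpi / self.dpi
        return replace(
            self,
            dot_radius_px=self.dot_radius_px * f,
            activation_margin_px=self.activation_margin_px * f,
            corridor_margin_px=self.corridor_margin_px * f,
            overshoot_threshold_px=self.overshoot_threshold_px * f,
            dpi=dpi,
        )


@dataclass
class ActiveDotSet:
    """Which of the five dots the respondent's ink touches."""

    active: tuple[bool, ...]
    evidence: tuple[int, ...]  # red pixels within the activation radius

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.active) if a)


@dataclass
class PixelAssignment:
    """Exclusive attribution of red pixels to candidate connections."""

    pixels_xy: np.ndarray             # (N, 2) float
    candidate_of: np.ndarray          # (N,) int index into `candidates`, -1 unassigned
    candidates: list[Connection]

    def pixels_for(self, cand_idx: int) -> np.ndarray:
        return self.pixels_xy[self.candidate_of == cand_idx]

    @property
    def unassigned_fraction(self) -> float:
        if len(self.candidate_of) == 0:
            return 0.0
        return float((self.candidate_of < 0).mean())


@dataclass
class RecognizedCell:
    """Recognition output for one cell."""

    cell_index: int
    true_connections: frozenset[Connection]
    design: int
    violations: int
    unassigned_fraction: float
    unscorable: bool
    diagnostics: dict[Connection, str] = field(default_factory=dict)


def _red_pixel_coords(cell: CellInk) -> np.ndarray:
    ys, xs = np.nonzero(cell.red_mask)
    return np.column_stack([xs, ys]).astype(float)


def identify_active_dots(cell: CellInk, config: RecognitionConfig) -> ActiveDotSet:
    """Task 1: a dot is active iff enough red pixels fall within its
    activation radius."""
    pts = _red_pixel_coords(cell)
    evidence = []
    for center in cell.dot_centers_px:
        if len(pts) == 0:
            evidence.append(0)
            continue
        d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        evidence.append(int((d <= config.activation_radius_px).sum()))
    active = tuple(e >= config.min_active_pixels for e in evidence)
    return ActiveDotSet(active=active, evidence=tuple(evidence))


def candidate_connections(active: ActiveDotSet) -> list[Connection]:
    """Task 2: every connection both of whose dots are active, in
    canonical order."""
    idx = set(active.indices)
    return [c for c in enumerate_connections(len(active.active))
            if c.dot_a in idx and c.dot_b in idx]


def _segment_geometry(centers: np.ndarray, conn: Connection):
    p = centers[conn.dot_a]
    q = centers[conn.dot_b]
    u = q - p
    length = float(np.hypot(*u))
    return p, q, u / length, length


def _point_segment_distance(pts: np.ndarray, p, u, length) -> tuple[np.ndarray, np.ndarray]:
    """Distances of points to a segment, plus signed projections along it."""
    rel = pts - p
    t = rel @ u
    tc = np.clip(t, 0.0, length)
    closest = p + tc[:, None] * u
    return np.hypot(*(pts - closest).T), t


def assign_pixels(
    cell: CellInk,
    candidates: list[Connection],
    config: RecognitionConfig,
) -> PixelAssignment:
    """Task 3: attribute each red pixel to the nearest candidate segment.

    A pixel farther than the corridor half-width from every candidate
    stays unassigned.  Distance ties (within 1e-6 px) go to the shorter
    segment, then to the lower canonical index, so assignment is
    deterministic.
    """
    pts = _red_pixel_coords(cell)
    n = len(pts)
    if not candidates or n == 0:
        return PixelAssignment(pts, np.full(n, -1, dtype=int), list(candidates))
    dists = np.empty((len(candidates), n))
    lengths = np.empty(len(candidates))
    for i, conn in enumerate(candidates):
        p, _, u, length = _segment_geometry(cell.dot_centers_px, conn)
        dists[i], _ = _point_segment_distance(pts, p, u, length)
        lengths[i] = length
    # preference order: distance, then segment length, then canonical index
    order = np.lexsort((
        [c.canonical_index for c in candidates], lengths))
    best = np.full(n, -1, dtype=int)
    best_d = np.full(n, np.inf)
    for i in order[::-1]:
        better = dists[i] <= best_d + 1e-6
        best[better] = i
        best_d[better] = np.minimum(best_d[better], dists[i][better])
    best[best_d > config.corridor_halfwidth_px] = -1
    return PixelAssignment(pts, best, list(candidates))


@dataclass
class CompatibilityResult:
    accepted: bool
    reason: str
    coverage: float
    max_gap_fraction: float


def check_line_compatibility(
    candidate: Connection,
    pixels_xy: np.ndarray,
    dot_centers: np.ndarray,
    config: RecognitionConfig,
) -> CompatibilityResult:
    """Task 4: do the assigned pixels actually form the candidate line?

    Projections of the pixels onto the segment are binned at 1 px; the
    candidate is accepted iff occupied bins cover at least
    ``coverage_threshold`` of the length and no empty run (including the
    ends) exceeds ``max_gap_fraction`` of it.
    """
    p, _, u, length = _segment_geometry(dot_centers, candidate)
    n_bins = max(int(np.ceil(length)), 1)
    if len(pixels_xy) == 0:
        return CompatibilityResult(False, "coverage", 0.0, 1.0)
    t = (pixels_xy - p) @ u
    bins = np.clip(np.floor(t).astype(int), 0, n_bins - 1)
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[bins] = True
    coverage = float(occupied.mean())
    # longest empty run, counting leading and trailing runs as gaps
    gaps = np.flatnonzero(occupied)
    longest = n_bins if gaps.size == 0 else max(
        gaps[0],                      # leading
        n_bins - 1 - gaps[-1],        # trailing
        int(np.max(np.diff(gaps)) - 1) if gaps.size > 1 else 0,
    )
    gap_frac = longest / n_bins
    if coverage < config.coverage_threshold:
        return CompatibilityResult(False, "coverage", coverage, gap_frac)
    if gap_frac > config.max_gap_fraction:
        return CompatibilityResult(False, "gap", coverage, gap_frac)
    return CompatibilityResult(True, "accepted", coverage, gap_frac)


def reject_false_positives(
    accepted: list[Connection],
    active: ActiveDotSet,
    assignment: PixelAssignment,
    dot_centers: np.ndarray,
    config: RecognitionConfig,
) -> tuple[set[Connection], dict[Connection, str]]:
    """Task 5: remove long candidates subsumed by collinear short ones.

    When an accepted candidate ``i-k`` passes within the activation
    radius of an interior active dot ``j`` and both ``i-j`` and ``j-k``
    are accepted, ``i-k`` is a false positive — the ink belongs to the
    two short strokes — unless it keeps enough pixels outside both short
    candidates' corridors (independent support).
    """
    accepted_set = set(accepted)
    notes: dict[Connection, str] = {}
    for conn in accepted:
        p, _, u, length = _segment_geometry(dot_centers, conn)
        for j in active.indices:
            if j in (conn.dot_a, conn.dot_b):
                continue
            d_j, _ = _point_segment_distance(dot_centers[None, j], p, u, length)
            if d_j[0] > config.activation_radius_px:
                continue
            short_a = _find(accepted_set, conn.dot_a, j)
            short_b = _find(accepted_set, j, conn.dot_b)
            if short_a is None or short_b is None:
                continue
            own = assignment.pixels_for(assignment.candidates.index(conn))
            support = _independent_support(own, dot_centers,
                                           (short_a, short_b), config)
            if support < config.min_independent_support_px:
                accepted_set.discard(conn)
                notes[conn] = "rejected:false_positive"
                break
    return accepted_set, notes


def _find(conns: set[Connection], a: int, b: int) -> Connection | None:
    lo, hi = min(a, b), max(a, b)
    for c in conns:
        if (c.dot_a, c.dot_b) == (lo, hi):
            return c
    return None


def _independent_support(pixels_xy, dot_centers, shorts, config) -> int:
    if len(pixels_xy) == 0:
        return 0
    outside = np.ones(len(pixels_xy), dtype=bool)
    for s in shorts:
        p, _, u, length = _segment_geometry(dot_centers, s)
        d, _ = _point_segment_distance(pixels_xy, p, u, length)
        outside &= d > config.corridor_halfwidth_px
    return int(outside.sum())


def detect_violations(
    cell: CellInk,
    connections: list[Connection],
    assignment: PixelAssignment,
    config: RecognitionConfig,
) -> set[Connection]:
    """Strokes that cross through their endpoint dots.

    For each connection, red pixels within the corridor of the *infinite*
    supporting line are examined; if ink extends more than
    ``overshoot_threshold_px`` beyond a dot center along the stroke
    direction, the stroke breached the "connect the dots" instruction.
    Pixels already attributed to another candidate are ignored so that
    other strokes meeting at the same dot cannot fake an overshoot.
    """
    pts = assignment.pixels_xy
    violating: set[Connection] = set()
    for conn in connections:
        p, _, u, length = _segment_geometry(cell.dot_centers_px, conn)
        cand_idx = (assignment.candidates.index(conn)
                    if conn in assignment.candidates else -2)
        usable = (assignment.candidate_of == cand_idx) | (assignment.candidate_of == -1)
        if not usable.any():
            continue
        rel = pts[usable] - p
        t = rel @ u
        perp = np.abs(rel @ np.array([-u[1], u[0]]))
        in_corridor = perp <= config.corridor_halfwidth_px
        if not in_corridor.any():
            continue
        t = t[in_corridor]
        overshoot = max(float(-t.min()), float(t.max() - length))
        if overshoot > config.overshoot_threshold_px:
            violating.add(conn)
    return violating


def recognize_cell(cell: CellInk, config: RecognitionConfig | None = None,
                   ) -> RecognizedCell:
    """Run all five tasks plus violation detection on one cell.

    A cell with red ink but neither true connections nor violations is
    marked unscorable (design 0) — typically stray marks or scribbles the
    algorithm cannot interpret as dot-to-dot lines.
    """
    config = config or RecognitionConfig()
    active = identify_active_dots(cell, config)
    candidates = candidate_connections(active)
    assignment = assign_pixels(cell, candidates, config)
    diagnostics: dict[Connection, str] = {}
    accepted: list[Connection] = []
    for i, conn in enumerate(candidates):
        result = check_line_compatibility(conn, assignment.pixels_for(i),
                                          cell.dot_centers_px, config)
        if result.accepted:
            accepted.append(conn)
            diagnostics[conn] = "accepted"
        else:
            diagnostics[conn] = f"rejected:{result.reason}"
    true_set, fp_notes = reject_false_positives(accepted, active, assignment,
                                                cell.dot_centers_px, config)
    diagnostics.update(fp_notes)
    violating = detect_violations(cell, sorted(true_set, key=lambda c: c.canonical_index),
                                  assignment, config)
    for conn in violating:
        diagnostics[conn] = "violation"
    if not config.count_violations_as_designs:
        true_set = true_set - violating
    design = design_id(true_set)
    has_ink = cell.n_red_pixels > 0
    unscorable = has_ink and design == 0 and len(violating) == 0
    return RecognizedCell(
        cell_index=cell.cell_index,
        true_connections=frozenset(true_set),
        design=design,
        violations=len(violating),
        unassigned_fraction=assignment.unassigned_fraction,
        unscorable=unscorable,
        diagnostics=diagnostics,
    )
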