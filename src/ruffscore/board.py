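"""Board model for the Ruff Figural Fluency Test (RFFT).

The RFFT protocol is five sheets ("parts"), each a 7 x 5 grid of 35
identical five-dot patterns.  The respondent connects dots with straight
strokes; because only 10 distinct unordered dot pairs exist, every
non-empty design is one of ``2**10 - 1 = 1023`` subsets of those
connections, and can be identified by a 10-bit mask (the *design ID*).

This module is pure geometry and combinatorics: dot layouts, cell boxes,
the canonical connection ordering and the design-ID encoding.  Nothing
here touches pixels.

Coordinates follow the raster convention: origin at the top-left, ``x``
rightward, ``y`` downward, 0-based indices.  Cells are indexed row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

N_ROWS = 7
N_COLS = 5
N_CELLS = N_ROWS * N_COLS
N_DOTS = 5
N_CONNECTIONS = 10
MAX_DESIGN_ID = 1023


class Connection(NamedTuple):
    """An unordered dot pair ``dot_a < dot_b`` with its canonical index.

    The canonical index is the rank of ``(dot_a, dot_b)`` in lexicographic
    order over all unordered pairs; for five dots it runs 0-9.  Design IDs
    set bit ``canonical_index`` for each present connection, so this
    ordering must never change between runs or layouts.
    """

    dot_a: int
    dot_b: int
    canonical_index: int


def enumerate_connections(n_dots: int = N_DOTS) -> list[Connection]:
    """All unordered dot pairs in canonical (lexicographic) order."""
    if n_dots < 2:
        raise ValueError(f"n_dots must be >= 2, got {n_dots}")
    return [
        Connection(a, b, idx)
        for idx, (a, b) in enumerate(combinations(range(n_dots), 2))
    ]


#: The ten canonical connections of the five-dot pattern.
CANONICAL_CONNECTIONS: tuple[Connection, ...] = tuple(enumerate_connections(N_DOTS))

_PAIR_TO_CONNECTION = {(c.dot_a, c.dot_b): c for c in CANONICAL_CONNECTIONS}


def as_connection(pair) -> Connection:
    """Coerce a ``Connection`` or ``(dot_a, dot_b)`` pair to canonical form."""
    if isinstance(pair, Connection):
        key = (pair.dot_a, pair.dot_b)
    else:
        a, b = pair
        key = (min(a, b), max(a, b))
    try:
        return _PAIR_TO_CONNECTION[key]
    except KeyError:
        raise ValueError(f"{pair!r} is not one of the 10 canonical connections")


def design_id(connections: Iterable) -> int:
    """Encode a set of connections as a 10-bit design ID.

    The empty set maps to 0, which denotes "no design" (blank or
    unscorable cell); every non-empty subset maps bijectively to 1-1023.
    """
    mask = 0
    for conn in connections:
        mask |= 1 << as_connection(conn).canonical_index
    return mask


def design_from_id(mask: int) -> frozenset[Connection]:
    """Decode a design ID back to its set of connections (inverse of
    :func:`design_id`)."""
    if not 0 <= mask <= MAX_DESIGN_ID:
        raise ValueError(f"design ID must be in 0..{MAX_DESIGN_ID}, got {mask}")
    return frozenset(c for c in CANONICAL_CONNECTIONS if mask >> c.canonical_index & 1)


def count_possible_designs(available: Sequence[Connection] | None = None) -> int:
    """Number of distinct non-empty designs, by explicit subset enumeration.

    With the full canonical set this is 1023.  ``available`` restricts the
    enumeration to a subset of connections (then ``2**len - 1``).
    """
    conns = tuple(CANONICAL_CONNECTIONS if available is None else available)
    count = 0
    for k in range(1, len(conns) + 1):
        for _subset in combinations(conns, k):
            count += 1
    return count


@dataclass(frozen=True)
class DotLayout:
    """Five-dot pattern of one part, in normalized cell coordinates.

    ``dot_positions`` live in the unit square (origin top-left, x right,
    y down).  Parts 2 and 3 carry printed distractors the respondent must
    ignore: small filled diamonds (part 2) or short line segments
    (part 3), both printed in black.
    """

    part_number: int
    dot_positions: tuple[tuple[float, float], ...]
    distractor_kind: str = "none"  # none | diamonds | lines
    #: diamonds: list of (x, y) centers; lines: list of (x1, y1, x2, y2)
    distractor_positions: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.part_number <= 5:
            raise ValueError(f"part_number must be 1..5, got {self.part_number}")
        pts = np.asarray(self.dot_positions, dtype=float)
        if pts.shape != (N_DOTS, 2):
            raise ValueError("exactly 5 dot positions required")
        if len({tuple(p) for p in self.dot_positions}) != N_DOTS:
            raise ValueError("dot positions must be pairwise distinct")
        if (pts < 0).any() or (pts > 1).any():
            raise ValueError("dot positions must lie in the unit square")
        expected = {2: "diamonds", 3: "lines"}.get(self.part_number, "none")
        if self.distractor_kind != expected:
            raise ValueError(
                f"part {self.part_number} requires distractor_kind="
                f"{expected!r}, got {self.distractor_kind!r}"
            )

    @property
    def dots(self) -> np.ndarray:
        return np.asarray(self.dot_positions, dtype=float)


@dataclass(frozen=True)
class BoardLayout:
    """Page and grid geometry of a full five-part protocol.

    All pixel quantities are at ``dpi``.  The 35 cell boxes tile a
    7-row x 5-column grid starting at ``(grid_x0, grid_y0)``; cell index
    ``row * 5 + col`` is row-major and 0-based.
    """

    dpi: float
    page_width_px: int
    page_height_px: int
    grid_x0: float
    grid_y0: float
    cell_width: float
    cell_height: float
    dot_radius_px: float
    parts: dict[int, DotLayout] = field(default_factory=dict)
    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    diamond_half_diag_px: float = 3.5
    line_width_px: float = 2.0

    def __post_init__(self) -> None:
        if sorted(self.parts) != [1, 2, 3, 4, 5]:
            raise ValueError("layout must define parts 1..5")
        if self.grid_x0 + self.n_cols * self.cell_width > self.page_width_px + 1e-6:
            raise ValueError("grid exceeds page width")
        if self.grid_y0 + self.n_rows * self.cell_height > self.page_height_px + 1e-6:
            raise ValueError("grid exceeds page height")

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Bounding box ``(x0, y0, x1, y1)`` of a cell in page coordinates."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) out of range")
        x0 = self.grid_x0 + col * self.cell_width
        y0 = self.grid_y0 + row * self.cell_height
        return (x0, y0, x0 + self.cell_width, y0 + self.cell_height)

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) out of range")
        return row * self.n_cols + col

    def cell_rowcol(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_rows * self.n_cols:
            raise ValueError(f"cell index {index} out of range")
        return divmod(index, self.n_cols)

    def dot_centers_cell(self, part: int) -> np.ndarray:
        """Dot centers of one cell in cell-local pixel coordinates, (5, 2) xy."""
        dots = self.parts[part].dots
        return dots * np.array([self.cell_width, self.cell_height])

    def dot_centers_page(self, part: int) -> np.ndarray:
        """Dot centers of all 35 cells in page coordinates, (35, 5, 2) xy."""
        local = self.dot_centers_cell(part)
        out = np.empty((self.n_rows * self.n_cols, N_DOTS, 2))
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                x0, y0, _, _ = self.cell_box(row, col)
                out[self.cell_index(row, col)] = local + np.array([x0, y0])
        return out

    def scaled(self, dpi: float) -> "BoardLayout":
        """The same physical layout re-expressed at another resolution."""
        f = dpi / self.dpi
        return BoardLayout(
            dpi=dpi,
            page_width_px=int(round(self.page_width_px * f)),
            page_height_px=int(round(self.page_height_px * f)),
            grid_x0=self.grid_x0 * f,
            grid_y0=self.grid_y0 * f,
            cell_width=self.cell_width * f,
            cell_height=self.cell_height * f,
            dot_radius_px=self.dot_radius_px * f,
            parts=dict(self.parts),
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            diamond_half_diag_px=self.diamond_half_diag_px * f,
            line_width_px=self.line_width_px * f,
        )


def min_interior_clearance(dots: np.ndarray) -> float:
    """Smallest distance from any dot to a connection segment it is not an
    endpoint of, in the same units as ``dots``.

    A healthy clearance (large relative to the activation radius) is what
    makes the 1023-design encoding recoverable from pixel evidence: no
    straight connection then grazes a third dot, so a drawn stroke
    activates exactly its two endpoint dots.
    """
    dots = np.asarray(dots, dtype=float)
    best = np.inf
    for conn in enumerate_connections(len(dots)):
        p, q = dots[conn.dot_a], dots[conn.dot_b]
        u = q - p
        lsq = float(u @ u)
        for c in range(len(dots)):
            if c in (conn.dot_a, conn.dot_b):
                continue
            t = float(np.clip((dots[c] - p) @ u / lsq, 0.0, 1.0))
            best = min(best, float(np.hypot(*(dots[c] - (p + t * u)))))
    return best


def _dotlayout_from_dict(part: int, entry: dict) -> DotLayout:
    kind = entry.get("distractor_kind", "none")
    raw = entry.get("distractors", [])
    return DotLayout(
        part_number=part,
        dot_positions=tuple(tuple(map(float, p)) for p in entry["dots"]),
        distractor_kind=kind,
        distractor_positions=tuple(tuple(map(float, d)) for d in raw),
    )


def load_layout(path=None) -> BoardLayout:
    """Load a board layout from YAML; the packaged default if ``path`` is None.

    The default approximates the commercial RFFT sheets (which are licensed
    artwork and not reproduced): a regular pentagon in parts 1-3 and
    irregular five-dot variants in parts 4-5, on an 8.5 x 11 inch page at
    300 dpi.
    """
    if path is None:
        ref = resources.files("ruffscore") / "layouts" / "default_rfft.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    parts = {int(k): _dotlayout_from_dict(int(k), v) for k, v in raw["parts"].items()}
    grid = raw["grid"]
    return BoardLayout(
        dpi=float(raw["dpi"]),
        page_width_px=int(raw["page_width_px"]),
        page_height_px=int(raw["page_height_px"]),
        grid_x0=float(grid["x0"]),
        grid_y0=float(grid["y0"]),
        cell_width=float(grid["cell_width"]),
        cell_height=float(grid["cell_height"]),
        dot_radius_px=float(raw["dot_radius_px"]),
        parts=parts,
        diamond_half_diag_px=float(raw.get("diamond_half_diag_px", 3.5)),
        line_width_px=float(raw.get("line_width_px", 2.0)),
    )
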