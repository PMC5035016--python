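"""RFFT scoring: unique designs, perseverative errors, violations.

Scanning a part's cells in drawing order, the first occurrence of a
design ID counts as a unique design and every repetition of an earlier
design in the same part counts as a perseverative error.  Equality is
strict design-ID equality (identical connection sets); rotated or
mirrored variants have different masks and are different designs.
Repetition is scoped within a part — the same design in two parts is
unique in both (a cross-part mode exists for sensitivity analyses).

Design 0 means blank or unscorable and enters neither tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .board import MAX_DESIGN_ID
from .recognize import RecognizedCell


class IncompleteProtocolError(ValueError):
    """A protocol is missing one or more of its five parts."""


@dataclass(frozen=True)
class PartScore:
    part_number: int
    unique_designs: int
    perseverative_errors: int
    violations: int
    attempted_cells: int
    unscorable_cells: int = 0


@dataclass(frozen=True)
class ProtocolScore:
    parts: tuple[PartScore, ...]

    @property
    def total_unique(self) -> int:
        return sum(p.unique_designs for p in self.parts)

    @property
    def total_perseverative(self) -> int:
        return sum(p.perseverative_errors for p in self.parts)

    @property
    def total_violations(self) -> int:
        return sum(p.violations for p in self.parts)

    @property
    def total_unscorable(self) -> int:
        return sum(p.unscorable_cells for p in self.parts)

    def part_unique(self) -> list[int]:
        return [p.unique_designs for p in self.parts]

    def part_perseverative(self) -> list[int]:
        return [p.perseverative_errors for p in self.parts]

    def as_row(self, protocol_id: str | None = None) -> dict:
        """Flat record for a CSV report."""
        row: dict = {} if protocol_id is None else {"protocol_id": protocol_id}
        for p in self.parts:
            row[f"unique_part{p.part_number}"] = p.unique_designs
            row[f"perseverative_part{p.part_number}"] = p.perseverative_errors
            row[f"violations_part{p.part_number}"] = p.violations
        row["total_unique"] = self.total_unique
        row["total_perseverative"] = self.total_perseverative
        row["total_violations"] = self.total_violations
        row["total_unscorable"] = self.total_unscorable
        return row


def score_part(
    designs: Sequence[int],
    part_number: int = 1,
    violations: Sequence[int] | None = None,
    unscorable: Sequence[bool] | None = None,
    seen: set[int] | None = None,
) -> PartScore:
    """Score one part from its ordered design IDs.

    ``seen`` carries already-encountered designs for the cross-part
    repetition mode; by default each part starts fresh.
    """
    if len(designs) > 35:
        raise ValueError("a part has at most 35 cells")
    seen_here = set() if seen is None else seen
    unique = perseverative = 0
    for d in designs:
        if not 0 <= d <= MAX_DESIGN_ID:
            raise ValueError(f"design ID {d} out of range")
        if d == 0:
            continue
        if d in seen_here:
            perseverative += 1
        else:
            seen_here.add(d)
            unique += 1
    return PartScore(
        part_number=part_number,
        unique_designs=unique,
        perseverative_errors=perseverative,
        violations=sum(violations) if violations else 0,
        attempted_cells=sum(1 for d in designs if d != 0),
        unscorable_cells=sum(bool(u) for u in unscorable) if unscorable else 0,
    )


def score_protocol(
    cells_by_part: Mapping[int, Sequence[RecognizedCell]],
    cross_part_perseveration: bool = False,
) -> ProtocolScore:
    """Score a full protocol of recognized cells.

    Cells must be in drawing order within each part.  Raises
    :class:`IncompleteProtocolError` when a part is missing.
    """
    missing = [p for p in range(1, 6) if p not in cells_by_part]
    if missing:
        raise IncompleteProtocolError(f"missing parts: {missing}")
    shared: set[int] | None = set() if cross_part_perseveration else None
    parts = []
    for part in range(1, 6):
        cells = cells_by_part[part]
        parts.append(score_part(
            [c.design for c in cells],
            part_number=part,
            violations=[c.violations for c in cells],
            unscorable=[c.unscorable for c in cells],
            seen=shared,
        ))
    return ProtocolScore(parts=tuple(parts))


def score_design_lists(
    designs_by_part: Mapping[int, Sequence[int]],
    violations_by_part: Mapping[int, Sequence[int]] | None = None,
    cross_part_perseveration: bool = False,
) -> ProtocolScore:
    """Score plain per-part design-ID lists (e.g. synthetic ground truth)."""
    missing = [p for p in range(1, 6) if p not in designs_by_part]
    if missing:
        raise IncompleteProtocolError(f"missing parts: {missing}")
    shared: set[int] | None = set() if cross_part_perseveration else None
    parts = []
    for part in range(1, 6):
        v = violations_by_part[part] if violations_by_part else None
        parts.append(score_part(designs_by_part[part], part_number=part,
                                violations=v, seen=shared))
    return ProtocolScore(parts=tuple(parts))
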