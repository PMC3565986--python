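"""Multiplex panel assembly for fluorescently labeled SSR markers.

Markers are co-amplified and co-electrophoresed in panels of up to three
loci.  Two markers can share a panel only if (a) they have the same motif
period — di-, tri- and tetra-nucleotide markers are never mixed, because
their stutter patterns and binning lattices differ — and (b) markers
carrying the same dye have allele-size ranges separated by a safety gap so
their peaks cannot be confused.  Forward primers carry one of three dyes
(6-FAM, HEX, NED); ROX is reserved for the internal size standard and is
not available for markers.

Panels are assembled by a deterministic greedy first-fit over markers
ranked by informativeness (PIC), mirroring the practice of ranking the
most informative markers first; global optimality is not attempted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MarkerDef",
    "Panel",
    "Violation",
    "DYES",
    "validate_panel",
    "assign_panels",
    "read_marker_table",
    "write_marker_table",
    "write_panel_table",
]

DYES = ("6-FAM", "HEX", "NED")

DEFAULT_MIN_GAP = 10  # bp between same-dye size ranges
DEFAULT_SIZE_HALO = 15  # ± bp around expected size when no observed range exists
DEFAULT_MAX_PER_PANEL = 3


@dataclass
class MarkerDef:
    """A named SSR marker with its primers, dye and size information.

    ``observed_size_range`` is the (min, max) of allele sizes seen in a
    genotyped panel; when absent, constraint checks fall back on
    ``expected_size`` ± a configured halo.  ``pic`` is the marker's
    polymorphism information content, used for ranking.
    """

    name: str
    forward_primer: str = ""
    reverse_primer: str = ""
    dye: str | None = None
    expected_size: int | None = None
    observed_size_range: tuple[int, int] | None = None
    period: int | None = None
    pic: float | None = None

    def __post_init__(self) -> None:
        if self.expected_size is not None and self.expected_size <= 0:
            raise ValueError(f"marker {self.name}: expected_size must be > 0")
        if self.observed_size_range is not None:
            lo, hi = self.observed_size_range
            if lo > hi:
                raise ValueError(f"marker {self.name}: size range min > max")
        if self.pic is not None and not 0 <= self.pic < 1:
            raise ValueError(f"marker {self.name}: pic outside [0, 1)")

    def size_range(self, halo: int = DEFAULT_SIZE_HALO) -> tuple[int, int]:
        if self.observed_size_range is not None:
            return self.observed_size_range
        if self.expected_size is not None:
            return (self.expected_size - halo, self.expected_size + halo)
        raise ValueError(f"marker {self.name}: no observed range and no expected size")


@dataclass
class Panel:
    """One multiplex: an id and an ordered list of member markers."""

    id: int
    members: list[MarkerDef] = field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    """A broken panel constraint; data, not an exception."""

    rule: str  # too_many_markers | mixed_period | dye_size_overlap
    markers: tuple[str, ...]


def validate_panel(
    panel: Panel,
    min_gap: int = DEFAULT_MIN_GAP,
    max_per_panel: int = DEFAULT_MAX_PER_PANEL,
    halo: int = DEFAULT_SIZE_HALO,
) -> list[Violation]:
    """All constraint violations in a panel (empty list = valid).

    Checks: at most ``max_per_panel`` members; a single motif period across
    members; and for every same-dye pair, size ranges separated by at least
    ``min_gap`` bp.  Markers on different dyes never conflict on size.
    """
    violations: list[Violation] = []
    members = panel.members
    if len(members) > max_per_panel:
        violations.append(
            Violation("too_many_markers", tuple(m.name for m in members))
        )
    periods = {m.period for m in members}
    if len(periods) > 1:
        violations.append(Violation("mixed_period", tuple(m.name for m in members)))
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if a.dye is None or b.dye is None or a.dye != b.dye:
                continue
            lo_a, hi_a = a.size_range(halo)
            lo_b, hi_b = b.size_range(halo)
            separation = max(lo_a, lo_b) - min(hi_a, hi_b)
            if separation < min_gap:
                violations.append(Violation("dye_size_overlap", (a.name, b.name)))
    return violations


def assign_panels(
    markers: Iterable[MarkerDef],
    max_per_panel: int = DEFAULT_MAX_PER_PANEL,
    min_gap: int = DEFAULT_MIN_GAP,
    rank_by: str = "pic",
    halo: int = DEFAULT_SIZE_HALO,
) -> list[Panel]:
    """Deterministic greedy first-fit panel assembly.

    Markers are sorted by the rank key — descending PIC (``rank_by="pic"``,
    ties broken by name ascending) or name ascending (``rank_by="name"``) —
    and each is placed into the lowest-id panel that stays violation-free,
    opening a new panel when none fits.  Every marker lands in exactly one
    panel and every returned panel validates clean under the same
    ``min_gap``/``halo``; the sort makes the result independent of input
    order.
    """
    markers = list(markers)
    for m in markers:
        if m.period is None:
            raise ValueError(f"marker {m.name}: period required for panel assignment")
        m.size_range(halo)  # raises if no size information at all
    if rank_by == "pic":
        missing = [m.name for m in markers if m.pic is None]
        if missing:
            raise ValueError(f"rank_by='pic' but markers missing pic: {missing}")
        ordered = sorted(markers, key=lambda m: (-m.pic, m.name))
    elif rank_by == "name":
        ordered = sorted(markers, key=lambda m: m.name)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}; use 'pic' or 'name'")
    panels: list[Panel] = []
    for marker in ordered:
        placed = False
        for panel in panels:
            panel.members.append(marker)
            if not validate_panel(panel, min_gap, max_per_panel, halo):
                placed = True
                break
            panel.members.pop()
        if not placed:
            panels.append(Panel(id=len(panels) + 1, members=[marker]))
    return panels


def min_panel_count(n_markers: int, max_per_panel: int = DEFAULT_MAX_PER_PANEL) -> int:
    """Pigeonhole lower bound on the number of panels."""
    return math.ceil(n_markers / max_per_panel) if n_markers else 0


# ---------------------------------------------------------------------------
# marker / panel tables (CSV)


def _opt_int(value: str) -> int | None:
    value = (value or "").strip()
    return int(value) if value else None


def _opt_float(value: str) -> float | None:
    value = (value or "").strip()
    return float(value) if value else None


def read_marker_table(path) -> list[MarkerDef]:
    """Marker definition CSV.

    Required column: ``marker``.  Recognized optional columns:
    ``forward_primer``, ``reverse_primer``, ``dye``, ``expected_size``,
    ``size_min``, ``size_max``, ``period``, ``pic``.
    """
    markers: list[MarkerDef] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "marker" not in reader.fieldnames:
            raise ValueError(f"{path}: marker table needs a 'marker' column")
        for row in reader:
            lo, hi = _opt_int(row.get("size_min", "")), _opt_int(row.get("size_max", ""))
            markers.append(
                MarkerDef(
                    name=row["marker"],
                    forward_primer=(row.get("forward_primer") or "").strip(),
                    reverse_primer=(row.get("reverse_primer") or "").strip(),
                    dye=(row.get("dye") or "").strip() or None,
                    expected_size=_opt_int(row.get("expected_size", "")),
                    observed_size_range=(lo, hi) if lo is not None and hi is not None else None,
                    period=_opt_int(row.get("period", "")),
                    pic=_opt_float(row.get("pic", "")),
                )
            )
    return markers


def write_marker_table(markers: Sequence[MarkerDef], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["marker", "forward_primer", "reverse_primer", "dye",
             "expected_size", "size_min", "size_max", "period", "pic"]
        )
        for m in markers:
            lo, hi = m.observed_size_range if m.observed_size_range else ("", "")
            writer.writerow(
                [m.name, m.forward_primer, m.reverse_primer, m.dye or "",
                 m.expected_size if m.expected_size is not None else "",
                 lo, hi,
                 m.period if m.period is not None else "",
                 f"{m.pic:.3f}" if m.pic is not None else ""]
            )


def write_panel_table(panels: Sequence[Panel], path, halo: int = DEFAULT_SIZE_HALO) -> None:
    """Panel definition CSV: panel id, marker, dye, size range, period."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["panel", "marker", "dye", "size_min", "size_max", "period"])
        for panel in panels:
            for m in panel.members:
                lo, hi = m.size_range(halo)
                writer.writerow([panel.id, m.name, m.dye or "", lo, hi, m.period])
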