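"""Invariant C. elegans lineage: named cells, division links, generations.

The early lineage is stereotyped: the zygote P0 (generation 0) divides into
AB and P1 (generation 1); the P line then successively buds off the somatic
founders EMS (-> MS, E), C and D, ending in the germline precursor P4.
Somatic daughters are named by appending an axis letter to the mother's name
(anterior/posterior here), e.g. ABa/ABp from AB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

#: Divisions whose daughter names are not formed by suffixing the mother.
SPECIAL_DAUGHTERS: dict[str, tuple[str, str]] = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
    # ABa and ABp divide along the left-right axis
    "ABa": ("ABal", "ABar"),
    "ABp": ("ABpl", "ABpr"),
}

FOUNDERS = ("AB", "MS", "E", "C", "D", "P")


def daughter_names(mother: str) -> tuple[str, str]:
    """Sulston-style daughter names for a mother cell."""
    if mother in SPECIAL_DAUGHTERS:
        return SPECIAL_DAUGHTERS[mother]
    return mother + "a", mother + "p"


def founder_lineage(name: str) -> str:
    """Founder lineage (AB, MS, E, C, D or P) a cell belongs to.

    The ancestral cells P0, P1, P2, P3, EMS are grouped with P (they are
    germline-line precursors / not yet committed to a somatic founder).
    """
    if name.startswith("AB"):
        return "AB"
    if name.startswith("MS"):
        return "MS"
    if name == "EMS" or name.startswith("P") or name.startswith("Z"):
        return "P"
    if name.startswith("E"):
        return "E"
    if name.startswith("C"):
        return "C"
    if name.startswith("D"):
        return "D"
    raise ValueError(f"cell name {name!r} does not map to a founder lineage")


@dataclass
class Cell:
    """One named cell in a lineage tree.

    ``anaphase_frame`` is the frame of anaphase onset (nuclear division);
    ``division_frame`` the frame at which cytokinesis completes and the
    daughters appear as separate segmented regions (anaphase plus the
    karyokinesis-cytokinesis lag). Both are ``None`` for cells whose cycle
    was not completed within the recording.
    """

    name: str
    parent: str | None
    birth_frame: int
    anaphase_frame: int | None = None
    division_frame: int | None = None

    @property
    def complete(self) -> bool:
        """Whether the full cell cycle (birth to division) was observed."""
        return self.anaphase_frame is not None


class LineageTree:
    """Named cells with parent/daughter links and frame-indexed cell cycles."""

    def __init__(self, cells: dict[str, Cell], n_frames: int, frame_interval_s: float = 30.0):
        self.cells = cells
        self.n_frames = n_frames
        self.frame_interval_s = frame_interval_s
        self._children: dict[str, list[str]] = {}
        for c in cells.values():
            if c.parent is not None:
                self._children.setdefault(c.parent, []).append(c.name)
        for v in self._children.values():
            v.sort()

    def __contains__(self, name: str) -> bool:
        return name in self.cells

    def __getitem__(self, name: str) -> Cell:
        return self.cells[name]

    def __iter__(self) -> Iterator[Cell]:
        return iter(self.cells.values())

    @property
    def dt_min(self) -> float:
        return self.frame_interval_s / 60.0

    def daughters(self, name: str) -> list[str]:
        return self._children.get(name, [])

    def generation(self, name: str) -> int:
        """Divisions separating a cell from the zygote (zygote = 0)."""
        g = 0
        c = self.cells[name]
        while c.parent is not None:
            g += 1
            c = self.cells[c.parent]
        return g

    def last_frame(self, name: str) -> int:
        """Last frame (inclusive) at which the cell exists as a region."""
        c = self.cells[name]
        if c.division_frame is None:
            return self.n_frames - 1
        return min(c.division_frame, self.n_frames) - 1

    def alive_at(self, frame: int) -> list[str]:
        """Names of cells existing as segmented regions at a frame."""
        return sorted(
            c.name
            for c in self.cells.values()
            if c.birth_frame <= frame <= self.last_frame(c.name)
        )

    def cycle_frames(self, name: str) -> int:
        """Cell cycle length in frames (birth to division, complete cells)."""
        c = self.cells[name]
        if c.division_frame is None:
            raise ValueError(f"cell {name} did not complete its cycle")
        return c.division_frame - c.birth_frame

    def complete_cells(self) -> list[str]:
        return sorted(c.name for c in self.cells.values() if c.complete)
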