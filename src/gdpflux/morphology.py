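"""Cylindrical-section neuronal morphologies.

A morphology is a tree of tapered cylindrical sections rooted at a single
soma section.  Geometry is in micrometres.  SWC import/export lives in
:mod:`gdpflux.swc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["Section", "Morphology", "MorphologyError"]


class MorphologyError(ValueError):
    pass


@dataclass
class Section:
    """A tapered cylinder.

    ``parent_position`` in [0, 1] gives the attachment point along the
    parent (1 = distal end).  ``region`` is "soma" or "dendrite".
    """

    id: int
    parent_id: int          # -1 for the root
    length: float           # um
    diam_prox: float        # um
    diam_dist: float        # um
    region: str = "dendrite"
    parent_position: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diam_prox <= 0 or self.diam_dist <= 0:
            raise MorphologyError("section lengths and diameters must be > 0")
        if not 0.0 <= self.parent_position <= 1.0:
            raise MorphologyError("parent_position must be in [0, 1]")
        if self.region not in ("soma", "dendrite"):
            raise MorphologyError(f"unknown region {self.region!r}")

    @property
    def mean_diam(self) -> float:
        return 0.5 * (self.diam_prox + self.diam_dist)

    @property
    def lateral_area(self) -> float:
        """Frustum lateral area (um^2); the membrane area of the section."""
        r1, r2 = self.diam_prox / 2, self.diam_dist / 2
        slant = math.hypot(self.length, r2 - r1)
        return math.pi * (r1 + r2) * slant

    @property
    def volume(self) -> float:
        """Frustum volume (um^3)."""
        r1, r2 = self.diam_prox / 2, self.diam_dist / 2
        return math.pi * self.length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


@dataclass
class Morphology:
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {s.id: s for s in self.sections}
        if len(by_id) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id == -1]
        if len(roots) != 1:
            raise MorphologyError("morphology must have exactly one root")
        if roots[0].region != "soma":
            raise MorphologyError("root section must be the soma")
        # tree check: every section reaches the root without cycles
        for s in self.sections:
            seen, cur = set(), s
            while cur.parent_id != -1:
                if cur.id in seen:
                    raise MorphologyError("cycle detected in morphology")
                seen.add(cur.id)
                if cur.parent_id not in by_id:
                    raise MorphologyError(f"missing parent {cur.parent_id}")
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id == -1)

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sec_id]

    @property
    def total_area(self) -> float:
        return sum(s.lateral_area for s in self.sections)

    @property
    def total_volume(self) -> float:
        return sum(s.volume for s in self.sections)

    def capacitance(self, cm: float = 1.0) -> float:
        """Total membrane capacitance (pF) at specific capacitance ``cm``
        in uF/cm^2 (1 uF/cm^2 over 1 um^2 is 0.01 pF)."""
        return 0.01 * cm * self.total_area

    def path_distance(self, sec_id: int) -> float:
        """Path length (um) from the soma surface to the distal end of a section."""
        by_id = {s.id: s for s in self.sections}
        d, cur = 0.0, by_id[sec_id]
        while cur.parent_id != -1:
            d += cur.length
            cur = by_id[cur.parent_id]
        return d
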