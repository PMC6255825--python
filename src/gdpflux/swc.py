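"""SWC reader/writer for cylindrical-section morphologies.

The standard 7-column SWC dialect is used: ``index type x y z radius
parent`` with 1-based indices and parent -1 for the root.  Type codes: 1 =
soma, 3 = (basal) dendrite.  On export the soma becomes a single root
point and each section contributes one point at its distal end; on import
each non-root point defines a tapered cylinder from its parent point, so
writer -> reader round-trips the section tree exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

from .morphology import Morphology, MorphologyError, Section

__all__ = ["read_swc", "write_swc"]

_TYPE_FOR_REGION = {"soma": 1, "dendrite": 3}
_REGION_FOR_TYPE = {1: "soma", 2: "dendrite", 3: "dendrite", 4: "dendrite"}


def write_swc(path: str | Path, morph: Morphology) -> None:
    """Write a morphology as SWC.

    Section coordinates are synthesized by laying each child section out
    radially from its attachment point; only topology, lengths and radii
    are semantically meaningful and only those survive a round trip.
    """
    by_id = {s.id: s for s in morph.sections}
    order = _topological_order(morph)
    swc_index: dict[int, int] = {}
    coords: dict[int, tuple[float, float, float]] = {}
    lines = []
    next_idx = 1
    for s in order:
        if s.parent_id == -1:
            # root soma: one point, radius = half mean diameter
            coords[s.id] = (0.0, 0.0, 0.0)
            lines.append(f"1 1 0.0 0.0 0.0 {s.mean_diam / 2:.6f} -1")
            swc_index[s.id] = next_idx
            next_idx += 1
            continue
        parent = by_id[s.parent_id]
        px, py, pz = coords[parent.id]
        # deterministic fan-out: rotate in the xy plane by the section id
        angle = 2.399963229728653 * s.id  # golden angle, avoids overlap
        ux, uy = math.cos(angle), math.sin(angle)
        x, y, z = px + ux * s.length, py + uy * s.length, pz
        coords[s.id] = (x, y, z)
        lines.append(
            f"{next_idx} {_TYPE_FOR_REGION[s.region]} "
            f"{x:.6f} {y:.6f} {z:.6f} {s.diam_dist / 2:.6f} {swc_index[parent.id]}"
        )
        swc_index[s.id] = next_idx
        next_idx += 1
    Path(path).write_text(
        "# SWC export (gdpflux)\n# index type x y z radius parent\n"
        + "\n".join(lines) + "\n"
    )


def read_swc(path: str | Path) -> Morphology:
    """Read an SWC file into a section tree.

    Every non-root point defines a tapered cylinder from its parent point
    to itself (proximal diameter from the parent radius, distal from its
    own).  The root point becomes a soma section of length and diameter
    equal to twice its radius.
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"malformed SWC line: {raw!r}")
        idx, typ = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        points[idx] = (typ, x, y, z, r, parent)
    if not points:
        raise MorphologyError("empty SWC file")

    sections: list[Section] = []
    for idx, (typ, x, y, z, r, parent) in sorted(points.items()):
        region = _REGION_FOR_TYPE.get(typ, "dendrite")
        if parent == -1:
            sections.append(Section(id=idx, parent_id=-1, length=2 * r,
                                    diam_prox=2 * r, diam_dist=2 * r,
                                    region="soma"))
            continue
        if parent not in points:
            raise MorphologyError(f"SWC point {idx} references missing parent")
        _, px, py, pz, pr, _ = points[parent]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            raise MorphologyError(f"zero-length SWC segment at point {idx}")
        prox = 2 * r if points[parent][0] == 1 else 2 * pr  # no soma taper
        sections.append(Section(id=idx, parent_id=parent, length=length,
                                diam_prox=prox, diam_dist=2 * r, region=region))
    return Morphology(sections=sections)


def _topological_order(morph: Morphology) -> list[Section]:
    by_parent: dict[int, list[Section]] = {}
    for s in morph.sections:
        by_parent.setdefault(s.parent_id, []).append(s)
    order, stack = [], [morph.root]
    while stack:
        s = stack.pop()
        order.append(s)
        stack.extend(sorted(by_parent.get(s.id, []), key=lambda c: -c.id))
    return order
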