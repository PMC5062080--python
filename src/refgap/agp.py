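"""Minimal AGP v2.1 writer.

Every output object (patched scaffold or chromosome) is described as an
ordered list of components: slices of source sequence (``W`` lines) and
N-gaps of known length (``N`` lines).  Component coordinates are converted to
AGP's 1-based inclusive convention at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union


@dataclass(frozen=True)
class SequenceComponent:
    """A slice [start, end) of a source sequence placed into an object."""

    source_id: str
    start: int
    end: int
    orientation: str = "+"  # '+', '-' or '?' (emitted as 'na')

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapComponent:
    """An N-run of stated length joining two sequence components."""

    length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "na"


Component = Union[SequenceComponent, GapComponent]


def component_length(c: Component) -> int:
    return c.length


def write_agp(objects: Mapping[str, Iterable[Component]], path: str | Path) -> None:
    lines = ["##agp-version\t2.1"]
    for object_id, components in objects.items():
        obj_pos = 0
        for part, comp in enumerate(components, start=1):
            beg, end = obj_pos + 1, obj_pos + comp.length
            if isinstance(comp, SequenceComponent):
                orient = "na" if comp.orientation == "?" else comp.orientation
                lines.append(
                    "\t".join(
                        [
                            object_id, str(beg), str(end), str(part), "W",
                            comp.source_id, str(comp.start + 1), str(comp.end), orient,
                        ]
                    )
                )
            else:
                lines.append(
                    "\t".join(
                        [
                            object_id, str(beg), str(end), str(part), "N",
                            str(comp.length), comp.gap_type, comp.linkage, comp.evidence,
                        ]
                    )
                )
            obj_pos = end
    Path(path).write_text("\n".join(lines) + "\n")


def read_agp(path: str | Path) -> dict[str, list[Component]]:
    """Inverse of :func:`write_agp`; used for audit round-trips in tests."""
    objects: dict[str, list[Component]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        comps = objects.setdefault(f[0], [])
        if f[4] == "W":
            orientation = "?" if f[8] == "na" else f[8]
            comps.append(SequenceComponent(f[5], int(f[6]) - 1, int(f[7]), orientation))
        else:
            comps.append(GapComponent(int(f[5]), f[6], f[7], f[8]))
    return objects
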