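"""Gene-set collections and the GMT interchange format.

GMT is one set per line: name, description, then the member identifiers,
all tab separated. Collections carry a free-text source label (e.g. the
MSigDB collection tag such as ``c2_cp`` or an Enrichr library name such as
``DisGeNET``); labels are pass-through strings, never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .containers import ValidationError


@dataclass
class GeneSetCollection:
    """name -> (description, member list), plus a source label."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene set name {name!r}")
        if len(set(members)) != len(members):
            raise ValidationError(f"gene set {name!r} has duplicate members")
        self.sets[name] = (description, list(members))


def read_gmt(path: str | Path, label: str = "") -> GeneSetCollection:
    """Parse a GMT file; malformed lines raise with the line number."""
    coll = GeneSetCollection(label=label or Path(path).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            coll.add(name, members, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
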