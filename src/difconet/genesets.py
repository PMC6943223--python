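"""Gene-set collections and the GMT format.

A collection is a mapping from set id to member gene ids over a declared
background universe, tagged as GO-like (significance by raw p) or
pathway-like (significance by FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

KINDS = ("go_like", "pathway_like")


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    kind: str = "go_like"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.universe = frozenset(self.universe)
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write tab-separated GMT: name, description, members (members sorted)."""
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "na")
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, universe=None, kind: str = "go_like") -> GeneSetCollection:
    """Read a GMT file; the universe defaults to the union of all members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, desc, *members = line.rstrip("\n").split("\t")
        sets[name] = frozenset(members)
        descriptions[name] = desc
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe), kind=kind, descriptions=descriptions)
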