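"""Typed gene-gene / pathway-pathway relation tables.

The vocabulary follows KEGG-style relation subtypes: activation (act),
inhibition (inh), binding/association (bin), compound (com), expression
(exp) and dissociation.  Binding and compound links are inherently
symmetric and are treated as undirected; the other four are directed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

RELATION_TYPES = ("act", "inh", "bin", "com", "exp", "dissociation")
UNDIRECTED_TYPES = frozenset({"bin", "com"})


@dataclass
class RelationTable:
    """Rows of (source, target, type, directed)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"source", "target", "type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"relation table missing columns: {sorted(missing)}")
        bad = set(self.table["type"]) - set(RELATION_TYPES)
        if bad:
            raise ValueError(f"unknown relation type(s): {sorted(bad)}")
        if "directed" not in self.table.columns:
            self.table = self.table.assign(
                directed=~self.table["type"].isin(UNDIRECTED_TYPES)
            )
        triples = self.table[["source", "target", "type"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (source, target, type) triples in relation table")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def write_relations(rel: RelationTable, path: str | Path) -> None:
    out = rel.table.copy()
    out["direction"] = out["directed"].map({True: "directed", False: "undirected"})
    out[["source", "target", "type", "direction"]].to_csv(path, sep="\t", index=False)


def read_relations(path: str | Path) -> RelationTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "direction" in table.columns:
        table["directed"] = table["direction"] == "directed"
        table = table.drop(columns=["direction"])
    return RelationTable(table)
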