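"""Rank-resolved taxonomy: parent links, genus genome-size medians, and
flags for genera whose monophyly is doubtful (e.g. *Candida* sensu lato).

The table format is a plain TSV with columns
``node  parent  rank  median_genome_size  unstable`` where ``parent`` is
empty for the root and ``median_genome_size`` / ``unstable`` are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RANKS = ("species", "genus", "family", "order", "class", "subphylum")


@dataclass
class Taxonomy:
    parent: dict[str, str | None] = field(default_factory=dict)
    rank: dict[str, str] = field(default_factory=dict)
    median_genome_size: dict[str, float] = field(default_factory=dict)
    unstable: set[str] = field(default_factory=set)

    def add_node(
        self,
        node: str,
        parent: str | None,
        rank: str,
        median_genome_size: float | None = None,
        unstable: bool = False,
    ) -> None:
        self.parent[node] = parent
        self.rank[node] = rank
        if median_genome_size is not None:
            self.median_genome_size[node] = float(median_genome_size)
        if unstable:
            self.unstable.add(node)

    def __contains__(self, node: str) -> bool:
        return node in self.parent

    def lineage(self, node: str) -> list[str]:
        """Path from ``node`` up to the root, inclusive."""
        if node not in self.parent:
            raise KeyError(f"taxon {node!r} not in taxonomy")
        path = [node]
        while (up := self.parent[path[-1]]) is not None:
            path.append(up)
        return path

    def ancestor_at(self, node: str, rank: str) -> str | None:
        """Ancestor of ``node`` (or node itself) carrying the given rank."""
        for anc in self.lineage(node):
            if self.rank.get(anc) == rank:
                return anc
        return None

    def lca(self, nodes: list[str]) -> str:
        """Lowest common ancestor of a non-empty node list."""
        if not nodes:
            raise ValueError("lca of an empty node list")
        common: list[str] | None = None
        for node in nodes:
            path = self.lineage(node)
            if common is None:
                common = path
            else:
                keep = set(path)
                common = [n for n in common if n in keep]
        assert common, "taxonomy has no single root"
        return common[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        tax = cls()
        for row in df.itertuples(index=False):
            size = getattr(row, "median_genome_size", "")
            flag = getattr(row, "unstable", "")
            tax.add_node(
                row.node,
                row.parent or None,
                row.rank,
                float(size) if size else None,
                str(flag).lower() in ("1", "true", "yes"),
            )
        return tax

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "node": n,
                "parent": self.parent[n] or "",
                "rank": self.rank[n],
                "median_genome_size": self.median_genome_size.get(n, ""),
                "unstable": "true" if n in self.unstable else "",
            }
            for n in self.parent
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
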