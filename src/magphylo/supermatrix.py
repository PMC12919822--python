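"""Single-copy-ortholog supermatrix construction.

The pipeline groups proteins into orthogroups (reciprocal-best-hit
clustering on shared residue k-mers — a deterministic, desk-scale
orthology engine; externally computed tables can be imported instead),
drops any group with a duplicated copy in some taxon, drops groups below
an occupancy threshold (present in at least ``min_fraction`` of the taxon
panel, boundary inclusive), and concatenates the surviving equal-length
loci into one residue matrix, padding absent (taxon, locus) cells with
gap characters and recording the per-locus column intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

GAP = "-"


@dataclass
class OrthoGroupTable:
    """group_id -> taxon -> protein ids (one or more copies)."""

    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def copy_counts(self) -> pd.DataFrame:
        """Group x taxon copy-count matrix (0 where absent)."""
        rows = {
            g: {t: len(p) for t, p in members.items()}
            for g, members in self.groups.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)

    def n_groups(self) -> int:
        return len(self.groups)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthoGroupTable":
        """Columns: group_id, taxon, protein_id (one row per copy)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        table = cls()
        for row in df.itertuples(index=False):
            table.groups.setdefault(row.group_id, {}).setdefault(
                row.taxon, []
            ).append(row.protein_id)
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"group_id": g, "taxon": t, "protein_id": p}
            for g in sorted(self.groups)
            for t in sorted(self.groups[g])
            for p in self.groups[g][t]
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class LocusAlignment:
    """Equal-length residue rows for one locus; absent taxa simply missing."""

    locus_id: str
    rows: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"locus {self.locus_id!r}: unequal row lengths {lengths}")


@dataclass
class SuperMatrix:
    taxa: list[str]
    rows: dict[str, str]
    partition_map: dict[str, tuple[int, int]]

    @property
    def n_columns(self) -> int:
        return sum(e - s for s, e in self.partition_map.values())

    def row(self, taxon: str) -> str:
        return self.rows[taxon]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.rows[t]}\n")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_columns}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.rows[t]}\n")

    def write_partitions(self, path: str | Path) -> None:
        """RAxML-style partition lines (1-based inclusive intervals)."""
        with open(path, "w") as fh:
            for locus, (s, e) in sorted(self.partition_map.items()):
                fh.write(f"PROT, {locus} = {s + 1}-{e}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SuperMatrix":
        rows = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        taxa = list(rows)
        ncol = len(next(iter(rows.values())))
        return cls(taxa, rows, {"all": (0, ncol)})


def _residue_kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def infer_orthogroups(
    proteomes: dict[str, dict[str, str]], k: int = 5, min_shared: int = 3
) -> OrthoGroupTable:
    """Reciprocal-best-hit orthogroup inference on shared residue k-mers.

    For each ordered taxon pair, the best hit of a protein is the partner
    protein sharing the most k-mers (ties -> lexicographically smallest
    protein id); hits sharing fewer than ``min_shared`` k-mers are
    discarded, so chance collisions between unrelated proteins never
    seed a group. Reciprocal best hits are merged by single-linkage.
    Deterministic and independent of input ordering.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    for taxon, prots in proteomes.items():
        if not prots:
            raise ValueError(f"proteome for {taxon!r} is empty")

    kmers = {
        taxon: {pid: _residue_kmers(seq, k) for pid, seq in prots.items()}
        for taxon, prots in proteomes.items()
    }

    def best_hit(taxon_from: str, pid: str, taxon_to: str) -> str | None:
        source = kmers[taxon_from][pid]
        best_pid, best_score = None, -1
        for qid in sorted(kmers[taxon_to]):
            score = len(source & kmers[taxon_to][qid])
            if score > best_score:
                best_pid, best_score = qid, score
        return best_pid if best_score >= min_shared else None

    # union-find over (taxon, protein) nodes
    parent: dict[tuple[str, str], tuple[str, str]] = {
        (t, p): (t, p) for t, prots in proteomes.items() for p in prots
    }

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    taxa = sorted(proteomes)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            for pid in sorted(proteomes[ta]):
                hit = best_hit(ta, pid, tb)
                if hit is not None and best_hit(tb, hit, ta) == pid:
                    union((ta, pid), (tb, hit))

    clusters: dict[tuple[str, str], dict[str, list[str]]] = {}
    for node in sorted(parent):
        clusters.setdefault(find(node), {}).setdefault(node[0], []).append(node[1])

    table = OrthoGroupTable()
    for i, root in enumerate(sorted(clusters)):
        table.groups[f"OG{i:05d}"] = clusters[root]
    return table


def single_copy_filter(table: OrthoGroupTable) -> OrthoGroupTable:
    """Drop any group where some represented taxon has 2+ copies."""
    kept = {
        g: members
        for g, members in table.groups.items()
        if all(len(pids) == 1 for pids in members.values())
    }
    return OrthoGroupTable(kept)


def occupancy_filter(
    table: OrthoGroupTable, n_taxa_total: int, min_fraction: float = 0.5
) -> OrthoGroupTable:
    """Keep groups present in at least ceil(min_fraction * n_taxa_total)
    taxa ("at least" is inclusive, so exactly 50% occupancy passes)."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    needed = math.ceil(min_fraction * n_taxa_total)
    kept = {
        g: members for g, members in table.groups.items() if len(members) >= needed
    }
    return OrthoGroupTable(kept)


def concatenate(loci: list[LocusAlignment], taxa: list[str]) -> SuperMatrix:
    """Gap-padded concatenation in lexicographic locus order.

    Loci are sorted by locus_id so the column layout does not depend on
    input-file ordering; absent (taxon, locus) cells become gap runs.
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    for locus in loci:
        locus.validate()
    ordered = sorted(loci, key=lambda lo: lo.locus_id)
    partition_map: dict[str, tuple[int, int]] = {}
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    col = 0
    for locus in ordered:
        length = locus.length
        partition_map[locus.locus_id] = (col, col + length)
        for t in taxa:
            parts[t].append(locus.rows.get(t, GAP * length))
        col += length
    return SuperMatrix(list(taxa), {t: "".join(parts[t]) for t in taxa}, partition_map)


def read_locus_fasta_dir(locus_dir: str | Path) -> list[LocusAlignment]:
    """One aligned FASTA per locus; records named by taxon."""
    loci = []
    for path in sorted(Path(locus_dir).glob("*.fasta")):
        rows = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        loci.append(LocusAlignment(path.stem, rows))
    return loci
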