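"""Candidate-bin screening against a yeast reference panel.

A bin (a MetaBAT2-style scaffold cluster) is screened by exact k-mer
containment against per-species reference k-mer sets — a deterministic,
desk-scale replacement for a BLASTN megablast search with a high bit-score
gate. Bins passing the screen are then subject to a genus genome-size
filter (drop if total length exceeds the genus median by more than the
tolerance; undersized bins are kept and handled by completeness) and a
single-copy marker completeness scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .taxonomy import Taxonomy

DEFAULT_K = 21
DEFAULT_MIN_CONTAINMENT = 0.30
DEFAULT_SIZE_TOLERANCE = 0.10


@dataclass
class Bin:
    """A candidate genome: a named collection of scaffold sequences."""

    bin_id: str
    scaffolds: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)

    @property
    def gc(self) -> float:
        total = self.total_length
        if total == 0:
            return 0.0
        gc = sum(s.upper().count("G") + s.upper().count("C") for _, s in self.scaffolds)
        return gc / total

    @property
    def n50(self) -> int:
        lengths = sorted((len(s) for _, s in self.scaffolds), reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for ln in lengths:
            acc += ln
            if acc >= half:
                return ln
        return 0

    @classmethod
    def from_fasta(cls, path: str | Path, bin_id: str | None = None) -> "Bin":
        path = Path(path)
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls(bin_id or path.stem, records)


@dataclass
class MarkerReport:
    n_markers: int
    single_copy: int
    duplicated: int
    missing: int

    @property
    def completeness(self) -> float:
        return self.single_copy / self.n_markers if self.n_markers else 0.0


def kmer_set(sequences: list[str], k: int = DEFAULT_K) -> frozenset[str]:
    """All forward k-mers (uppercased) across the given sequences."""
    kmers: set[str] = set()
    for seq in sequences:
        s = seq.upper()
        kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return frozenset(kmers)


def reference_db_from_fasta_dir(
    refdir: str | Path, k: int = DEFAULT_K
) -> dict[str, frozenset[str]]:
    """One k-mer set per reference species; species id = FASTA file stem."""
    db = {}
    for path in sorted(Path(refdir).glob("*.fasta")):
        seqs = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
        db[path.stem] = kmer_set(seqs, k)
    return db


def screen_bin(
    bin_: Bin,
    reference_db: dict[str, frozenset[str]],
    k: int = DEFAULT_K,
    min_containment: float = DEFAULT_MIN_CONTAINMENT,
) -> tuple[str, float] | None:
    """Best species hit by k-mer containment, or None (reject).

    containment(species) = |bin ∩ ref| / |bin k-mers|. Containment is a
    fraction of the bin's own k-mers, so duplicating scaffolds leaves the
    score unchanged. Ties break to the lexicographically first species id.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not reference_db:
        raise ValueError("reference database is empty")
    bin_kmers = kmer_set([s for _, s in bin_.scaffolds], k)
    if not bin_kmers:
        raise ValueError(f"bin {bin_.bin_id!r} has no sequence of length >= k")
    best_species, best_score = None, -1.0
    for species in sorted(reference_db):
        score = len(bin_kmers & reference_db[species]) / len(bin_kmers)
        if score > best_score:
            best_species, best_score = species, score
    if best_score >= min_containment:
        assert best_species is not None
        return best_species, best_score
    return None


def size_filter(
    bin_: Bin,
    assigned_genus: str,
    taxonomy: Taxonomy,
    tolerance: float = DEFAULT_SIZE_TOLERANCE,
) -> bool:
    """True = keep. Drop only if total length is *strictly more than*
    (1 + tolerance) x the genus median genome size; undersized bins pass."""
    median = taxonomy.median_genome_size.get(assigned_genus)
    if median is None:
        raise ValueError(f"genus {assigned_genus!r} has no median genome size")
    return not (bin_.total_length > (1.0 + tolerance) * median)


def marker_completeness(
    bin_protein_ids: list[str] | dict[str, int],
    marker_orthogroups: dict[str, set[str]],
) -> MarkerReport:
    """Count marker copies in a bin's protein set.

    ``marker_orthogroups`` maps marker id -> protein ids belonging to the
    marker; a bin protein counts toward a marker if its id is in that set.
    0 copies -> missing, 1 -> single copy, >=2 -> duplicated.
    """
    if not marker_orthogroups:
        raise ValueError("marker set is empty")
    if isinstance(bin_protein_ids, dict):
        counts_by_protein = bin_protein_ids
    else:
        counts_by_protein = {}
        for pid in bin_protein_ids:
            counts_by_protein[pid] = counts_by_protein.get(pid, 0) + 1
    single = dup = missing = 0
    for members in marker_orthogroups.values():
        copies = sum(counts_by_protein.get(pid, 0) for pid in members)
        if copies == 0:
            missing += 1
        elif copies == 1:
            single += 1
        else:
            dup += 1
    return MarkerReport(len(marker_orthogroups), single, dup, missing)
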