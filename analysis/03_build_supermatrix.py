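"""Infer orthogroups across reference and query proteomes, apply the
single-copy and occupancy filters, and write the concatenated supermatrix
to results/supermatrix.*"""

import argparse
from pathlib import Path

from Bio import SeqIO

from magphylo.supermatrix import (
    LocusAlignment,
    concatenate,
    infer_orthogroups,
    occupancy_filter,
    single_copy_filter,
)


def load_proteomes(synth: Path) -> dict[str, dict[str, str]]:
    proteomes = {}
    for path in sorted((synth / "proteomes").glob("*.fasta")):
        proteomes[path.stem] = {
            r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")
        }
    for path in sorted((synth / "bins").glob("*.proteins.fasta")):
        taxon = path.name.removesuffix(".proteins.fasta")
        proteomes[taxon] = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    return proteomes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--min-fraction", type=float, default=0.5)
    args = parser.parse_args()

    proteomes = load_proteomes(args.results / "synthetic")
    og = infer_orthogroups(proteomes)
    sc = single_copy_filter(og)
    occ = occupancy_filter(sc, n_taxa_total=len(proteomes), min_fraction=args.min_fraction)
    print(
        f"orthogroups: {og.n_groups()} inferred, {sc.n_groups()} single-copy, "
        f"{occ.n_groups()} after occupancy filter"
    )
    loci = [
        LocusAlignment(gid, {t: proteomes[t][pids[0]] for t, pids in members.items()})
        for gid, members in occ.groups.items()
    ]
    sm = concatenate(loci, sorted(proteomes))
    prefix = args.results / "supermatrix"
    sm.write_fasta(f"{prefix}.fasta")
    sm.write_phylip(f"{prefix}.phy")
    sm.write_partitions(f"{prefix}.partitions.txt")
    og.to_tsv(args.results / "orthogroups.tsv")
    print(f"supermatrix: {len(sm.taxa)} taxa x {sm.n_columns} columns -> {prefix}.*")


if __name__ == "__main__":
    main()
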