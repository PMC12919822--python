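"""Screen the simulated query bins against the reference panel by k-mer
containment; write results/screen_results.tsv."""

import argparse
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from magphylo.screen import Bin, kmer_set, screen_bin
from magphylo.synthgen import back_translate, from_residues


def reference_db_from_proteomes(proteome_dir: Path) -> dict[str, frozenset[str]]:
    """Back-translate each reference proteome to a nucleotide k-mer set."""
    db = {}
    for path in sorted(proteome_dir.glob("*.fasta")):
        seqs = [
            back_translate(from_residues(str(r.seq)))
            for r in SeqIO.parse(str(path), "fasta")
        ]
        db[path.stem] = kmer_set(seqs)
    return db


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    synth = args.results / "synthetic"
    db = reference_db_from_proteomes(synth / "proteomes")
    rows = []
    for path in sorted((synth / "bins").glob("*.fasta")):
        if path.name.endswith(".proteins.fasta"):
            continue
        b = Bin.from_fasta(path)
        hit = screen_bin(b, db)
        rows.append(
            {
                "bin_id": b.bin_id,
                "total_length": b.total_length,
                "n50": b.n50,
                "species": hit[0] if hit else "",
                "containment": round(hit[1], 4) if hit else 0.0,
                "passed": hit is not None,
            }
        )
    out = args.results / "screen_results.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
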