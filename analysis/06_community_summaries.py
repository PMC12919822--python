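"""Community summaries: presence matrices, genus co-occurrence, per-MAG
depth metrics, and the contig length-vs-depth scatter. Writes under
results/community/."""

import argparse
from pathlib import Path

import pandas as pd

from magphylo.classify import Assignment
from magphylo.community import (
    abundance_points,
    build_presence,
    cooccurrence,
    depth_summary,
    plot_abundance,
)
from magphylo.datasets import coffee_assignments
from magphylo.pipeline import example_config


def synthetic_assignments(results: Path) -> list[Assignment]:
    df = pd.read_csv(results / "assignments_synthetic.tsv", sep="\t")
    return [
        Assignment(r.query_id, r.category, r.rank, str(r.label), str(r.label))
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    outdir = args.results / "community"
    outdir.mkdir(parents=True, exist_ok=True)

    # coffee worked example: presence + co-occurrence
    coffee = coffee_assignments()
    species = build_presence(coffee, rank="species")
    genus = build_presence(coffee, rank="genus")
    species.to_csv(outdir / "coffee_presence_species.tsv", sep="\t")
    genus.to_csv(outdir / "coffee_presence_genus.tsv", sep="\t")
    co = cooccurrence(genus)
    co.to_csv(outdir / "coffee_cooccurrence_genus.tsv", sep="\t", index=False)
    richness = species.sum(axis=1)
    print(f"per-sample species richness:\n{richness.to_string()}")
    cross = co[co.taxon_a != co.taxon_b]
    print(f"top genus pair: {cross.iloc[0].to_dict()}")

    # synthetic community: depth summaries + abundance scatter
    config = example_config(seed=args.seed)
    depth = pd.read_csv(args.results / "synthetic" / "depth_tables.tsv", sep="\t")
    rows = []
    for member in config.community_specs:
        sub = depth[(depth["sample"] == member.sample) & (depth["scaffold"] == member.member)]
        s = depth_summary(sub, member.member, member.genome_length)
        rows.append({"sample": member.sample, **vars(s)})
    summaries = pd.DataFrame(rows)
    summaries.to_csv(outdir / "synthetic_mag_summaries.tsv", sep="\t", index=False)
    print(summaries.to_string(index=False))

    scaffold_rows = []
    assignments = {a.query_id: a.label for a in synthetic_assignments(args.results)}
    from Bio import SeqIO

    for path in sorted((args.results / "synthetic" / "bins").glob("*.fasta")):
        if path.name.endswith(".proteins.fasta"):
            continue
        qid = path.stem
        mean = next(
            (m.mean_depth for m in config.community_specs if m.member == qid), 1.0
        )
        for r in SeqIO.parse(str(path), "fasta"):
            scaffold_rows.append(
                {"scaffold": r.id, "length": len(r.seq), "mean_depth": mean,
                 "taxon": assignments.get(qid, "unassigned")}
            )
    table = pd.DataFrame(scaffold_rows)
    pts = abundance_points(table, dict(zip(table["scaffold"], table["taxon"])))
    pts.to_csv(outdir / "abundance_points.tsv", sep="\t", index=False)
    plot_abundance(pts, outdir / "abundance_scatter.png")
    print(f"{len(pts)} scaffolds >= 4 kb plotted -> {outdir / 'abundance_scatter.png'}")


if __name__ == "__main__":
    main()
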