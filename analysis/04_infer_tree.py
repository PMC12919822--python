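"""Neighbor-joining tree with bootstrap supports from the supermatrix,
rooted on the outgroup; writes results/tree.nwk."""

import argparse
from pathlib import Path

from magphylo.supermatrix import SuperMatrix
from magphylo.synthgen import OUTGROUP_LABEL
from magphylo.treekit import bootstrap_support, root_tree, write_newick


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--bootstrap", type=int, default=100)
    parser.add_argument("--outgroup", type=str, default=OUTGROUP_LABEL)
    args = parser.parse_args()

    sm = SuperMatrix.from_fasta(args.results / "supermatrix.fasta")
    tree = bootstrap_support(sm, n_reps=args.bootstrap, seed=args.seed)
    tree = root_tree(tree, args.outgroup)
    out = args.results / "tree.nwk"
    write_newick(tree, out)
    print(f"tree with {len(sm.taxa)} leaves, {args.bootstrap} bootstrap reps -> {out}")


if __name__ == "__main__":
    main()
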