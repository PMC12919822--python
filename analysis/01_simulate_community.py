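"""Generate the seeded synthetic community (reference panel, query MAGs,
depth tables) into results/synthetic/."""

import argparse
from pathlib import Path

from magphylo.pipeline import example_config
from magphylo.synthgen import generate_all


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    outdir = args.results / "synthetic"
    config = example_config(seed=args.seed)
    generate_all(config, outdir=outdir)
    print(f"synthetic scenario (seed {args.seed}) -> {outdir}")


if __name__ == "__main__":
    main()
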