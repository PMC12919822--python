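"""Per-MAG coverage metrics and cross-sample community summaries.

From sparse per-base depth tables this module computes mean depth,
breadth of coverage, and strain-heterogeneity (alternate-allele) counts
per MAG; from classification results it builds sample x taxon presence
matrices, pairwise co-occurrence tallies, and the contig length-vs-depth
table used for abundance scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import REJECTED, Assignment, sample_of

DEFAULT_ALT_MIN_COUNT = 2
DEFAULT_ALT_MIN_FRACTION = 0.1
DEFAULT_MIN_SCAFFOLD_LENGTH = 4000


@dataclass
class MagSummary:
    mag_id: str
    mean_depth: float
    breadth: float
    alt_alleles: int
    total_length: int


def depth_summary(
    table: pd.DataFrame,
    mag_id: str,
    total_length: int,
    alt_min_count: int = DEFAULT_ALT_MIN_COUNT,
    alt_min_fraction: float = DEFAULT_ALT_MIN_FRACTION,
) -> MagSummary:
    """Summarize a sparse per-base depth table for one MAG.

    Positions absent from the table count as depth 0 toward the mean and
    as uncovered toward breadth. A position is a heterogeneous
    (alternate-allele) site when alt_count >= ``alt_min_count`` AND
    alt_count / depth >= ``alt_min_fraction`` — the two-knob rule
    suppresses singleton errors while catching >=10% minor strains.
    """
    if (table["alt_count"] > table["depth"]).any():
        raise ValueError("alt_count exceeds depth in the table")
    depth = table["depth"].to_numpy()
    alt = table["alt_count"].to_numpy()
    covered = int((depth >= 1).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    het = int(((alt >= alt_min_count) & (frac >= alt_min_fraction)).sum())
    return MagSummary(
        mag_id=mag_id,
        mean_depth=float(depth.sum()) / total_length,
        breadth=covered / total_length,
        alt_alleles=het,
        total_length=total_length,
    )


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Depth table TSV with columns scaffold, pos (1-based), depth,
    alt_count."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# presence / co-occurrence


def _presence_label(a: Assignment, rank: str) -> str:
    if rank == "genus":
        return a.genus_label
    # species rank: resolve novel / family-level calls to a distinct label
    if a.rank == "species":
        return a.label
    return f"{a.label} sp."


def build_presence(
    assignments: list[Assignment], rank: str = "species"
) -> pd.DataFrame:
    """Sample x taxon boolean matrix from non-rejected assignments.

    Sample ids come from query-id prefixes; novel / provisional /
    family-level calls contribute their resolved-rank label.
    """
    if rank not in ("species", "genus"):
        raise ValueError("rank must be species or genus")
    cells = set()
    for a in assignments:
        if a.category == REJECTED:
            continue
        cells.add((sample_of(a.query_id), _presence_label(a, rank)))
    samples = sorted({s for s, _ in cells})
    taxa = sorted({t for _, t in cells})
    matrix = pd.DataFrame(False, index=samples, columns=taxa)
    for s, t in cells:
        matrix.at[s, t] = True
    return matrix


def cooccurrence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample counts for every unordered taxon pair (self-pairs =
    prevalence), with the share of samples as a rounded percent.

    Sorted by descending count, then lexicographically.
    """
    n_samples = len(matrix.index)
    if n_samples < 1:
        raise ValueError("presence matrix has no samples")
    rows = []
    taxa = list(matrix.columns)
    for a, b in combinations(taxa, 2):
        count = int((matrix[a] & matrix[b]).sum())
        rows.append((a, b, count))
    for t in taxa:
        rows.append((t, t, int(matrix[t].sum())))
    out = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "count"])
    out["percent"] = (100.0 * out["count"] / n_samples).round().astype(int)
    return out.sort_values(
        ["count", "taxon_a", "taxon_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# abundance scatter data


def abundance_points(
    scaffold_table: pd.DataFrame,
    taxon_by_scaffold: dict[str, str] | None = None,
    min_length: int = DEFAULT_MIN_SCAFFOLD_LENGTH,
) -> pd.DataFrame:
    """Plot-ready (length, depth, taxon) rows for scaffolds >= min_length.

    ``scaffold_table`` needs columns scaffold, length, mean_depth. The
    length cut is inclusive (a 4,000 bp scaffold passes at the default);
    unmapped scaffolds are labeled "unassigned". Log transforms are left
    to the plotting layer.
    """
    taxon_by_scaffold = taxon_by_scaffold or {}
    kept = scaffold_table[scaffold_table["length"] >= min_length].copy()
    kept["taxon"] = [
        taxon_by_scaffold.get(s, "unassigned") for s in kept["scaffold"]
    ]
    return kept.reset_index(drop=True)


def plot_abundance(points: pd.DataFrame, path: str | Path) -> None:
    """Length-vs-depth scatter on log2 axes, colored by taxon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for taxon, group in points.groupby("taxon"):
        ax.scatter(
            np.log2(group["mean_depth"].clip(lower=0.01)),
            np.log2(group["length"]),
            s=12,
            alpha=0.7,
            label=taxon,
        )
    ax.set_xlabel("log2 mean depth (x)")
    ax.set_ylabel("log2 scaffold length (bp)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
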