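"""End-to-end driver: synthetic scenario -> supermatrix -> tree -> calls.

Chains the generators and the analysis modules so a whole seeded study
(reference panel, query MAGs, depth tables) can be run and checked
against its ground truth in one call. This is the path the analysis
scripts and the acceptance checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import synthgen
from .classify import Assignment, ClassifyParams, classify_all
from .community import MagSummary, build_presence, depth_summary
from .supermatrix import (
    LocusAlignment,
    OrthoGroupTable,
    SuperMatrix,
    concatenate,
    infer_orthogroups,
    occupancy_filter,
    single_copy_filter,
)
from .synthgen import OUTGROUP_LABEL, SimConfig, to_residues
from .taxonomy import Taxonomy
from .treekit import bootstrap_support, root_tree


def example_config(seed: int = 1) -> SimConfig:
    """The canonical benchmark scenario: a 12-taxon reference panel,
    50 loci of 200 residues with 90% occupancy, and five query MAGs at
    divergences spanning the conspecific / provisional / family-level /
    rejected regimes, spread over three samples with one strain-mixed
    member."""
    from .synthgen import CommunityMember, QuerySpec

    return SimConfig(
        seed=seed,
        n_ref_taxa=12,
        n_loci=50,
        locus_length=200,
        birth_rate=1.0,
        occupancy_prob=0.9,
        query_specs=[
            QuerySpec("CF01_bin_1", "T03", 0.005),
            QuerySpec("CF02_bin_1", "T05", 0.005),
            QuerySpec("CF02_bin_2", "T07", 0.05),
            QuerySpec("CF03_bin_1", "T09", 0.15),
            QuerySpec("CF03_bin_2", "T02", 0.5),
        ],
        community_specs=[
            CommunityMember("CF01", "CF01_bin_1", 50.0, 100_000, 0.3, 0.01),
            CommunityMember("CF02", "CF02_bin_1", 20.0, 100_000),
            CommunityMember("CF02", "CF02_bin_2", 12.0, 100_000),
            CommunityMember("CF03", "CF03_bin_1", 8.0, 100_000),
        ],
    )


def synthetic_taxonomy(panel_taxa: list[str]) -> Taxonomy:
    """One-genus-per-species taxonomy for a synthetic reference panel."""
    tax = Taxonomy()
    tax.add_node("SynthSubphylum", None, "subphylum")
    tax.add_node("SynthClass", "SynthSubphylum", "class")
    tax.add_node("SynthOrder", "SynthClass", "order")
    tax.add_node("SynthFamily", "SynthOrder", "family")
    tax.add_node("OutgroupFamily", "SynthOrder", "family")
    for taxon in panel_taxa:
        family = "OutgroupFamily" if taxon == OUTGROUP_LABEL else "SynthFamily"
        tax.add_node(f"G_{taxon}", family, "genus", 1e7)
        tax.add_node(taxon, f"G_{taxon}", "species")
    return tax


@dataclass
class PipelineResult:
    generated: dict
    orthogroups: OrthoGroupTable
    orthogroups_single_copy: OrthoGroupTable
    orthogroups_occupancy: OrthoGroupTable
    matrix: SuperMatrix
    tree: object
    assignments: list[Assignment]
    tally: pd.DataFrame
    presence: pd.DataFrame
    mag_summaries: dict[tuple[str, str], MagSummary] = field(default_factory=dict)


def proteomes_from_generated(generated: dict) -> dict[str, dict[str, str]]:
    """Panel + query proteomes as taxon -> protein_id -> residues."""
    proteomes: dict[str, dict[str, str]] = {}
    for taxon, by_locus in generated["panel_reduced"].items():
        proteomes[taxon] = {
            f"{taxon}|{locus}": to_residues(seq) for locus, seq in by_locus.items()
        }
    for qid, mag in generated["queries"].items():
        proteomes[qid] = {
            f"{qid}|{locus}": to_residues(seq) for locus, seq in mag.proteome.items()
        }
    return proteomes


def loci_from_orthogroups(
    table: OrthoGroupTable, proteomes: dict[str, dict[str, str]]
) -> list[LocusAlignment]:
    """Single-copy orthogroups as equal-length locus alignments."""
    loci = []
    for group_id, members in table.groups.items():
        rows = {
            taxon: proteomes[taxon][pids[0]] for taxon, pids in members.items()
        }
        loci.append(LocusAlignment(group_id, rows))
    return loci


def run_synthetic(
    config: SimConfig,
    params: ClassifyParams | None = None,
    bootstrap_reps: int = 100,
    min_occupancy: float = 0.5,
) -> PipelineResult:
    """Generate a scenario and run screening-to-classification on it."""
    params = params or ClassifyParams()
    generated = synthgen.generate_all(config)
    proteomes = proteomes_from_generated(generated)

    og = infer_orthogroups(proteomes)
    sc = single_copy_filter(og)
    occ = occupancy_filter(sc, n_taxa_total=len(proteomes), min_fraction=min_occupancy)
    matrix = concatenate(loci_from_orthogroups(occ, proteomes), sorted(proteomes))

    tree = bootstrap_support(matrix, n_reps=bootstrap_reps, seed=config.seed)
    tree = root_tree(tree, OUTGROUP_LABEL)

    panel_taxa = sorted(generated["panel"])
    taxonomy = synthetic_taxonomy(panel_taxa)
    query_ids = sorted(generated["queries"])
    assignments, tally_df = classify_all(tree, query_ids, taxonomy, params)

    presence = build_presence(assignments, rank="species")

    summaries = {}
    for (sample, member), table in generated["pileups"].items():
        spec = next(
            m for m in config.community_specs
            if m.sample == sample and m.member == member
        )
        summaries[(sample, member)] = depth_summary(table, member, spec.genome_length)

    return PipelineResult(
        generated=generated,
        orthogroups=og,
        orthogroups_single_copy=sc,
        orthogroups_occupancy=occ,
        matrix=matrix,
        tree=tree,
        assignments=assignments,
        tally=tally_df,
        presence=presence,
        mag_summaries=summaries,
    )


def category_accuracy(result: PipelineResult) -> float:
    """Fraction of queries whose category matches the ground truth."""
    truth = result.generated["truth"].true_assignments
    hits = sum(
        1
        for a in result.assignments
        if truth[a.query_id][0] == a.category
    )
    return hits / len(result.assignments) if result.assignments else 1.0
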