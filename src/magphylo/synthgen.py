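"""Synthetic inputs with known ground truth for the whole pipeline.

Real coffee-fermentation metagenomes are not redistributable, so every
input the pipeline consumes can be simulated here from one seeded
configuration: a Yule species tree with an outgroup (the reference
panel), proteomes evolved along it under a 20-state equal-rates model
with per-locus occupancy dropout, query MAGs at controlled divergence /
completeness / contamination from chosen references, nucleotide
scaffolds with lognormal lengths, and per-base depth tables with
negative-binomial depth and strain-mixture alternate alleles.

All randomness flows from a single root seed through named substreams,
so adding a generator never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.model import birthdeath

from ._rng import py_substream, substream

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
OUTGROUP_LABEL = "OUTGROUP"
# tree scale in substitutions/site: deep enough to emulate a
# subphylum-wide reference panel, shallow enough that orthologs stay
# detectable by k-mer similarity. Curated panels hold distinct species,
# so terminal branches get an interspecies floor.
OUTGROUP_BRANCH = 0.20
DEFAULT_TREE_DEPTH = 0.50
MIN_TERMINAL_BRANCH = 0.05

# one fixed codon per residue; nucleotide realism is not needed downstream
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class QuerySpec:
    query_id: str
    reference: str
    divergence: float
    completeness: float = 1.0
    contamination: float = 0.0
    chimera_with: str | None = None  # second parent for a chimeric MAG

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if not (0 < self.completeness <= 1):
            raise ValueError("completeness must be in (0, 1]")


@dataclass
class CommunityMember:
    sample: str
    member: str  # query id or reference taxon
    mean_depth: float
    genome_length: int = 200_000
    strain_fraction: float = 0.0
    strain_divergence: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    n_ref_taxa: int = 12
    n_loci: int = 50
    locus_length: int = 200
    birth_rate: float = 1.0
    occupancy_prob: float = 0.9
    query_specs: list[QuerySpec] = field(default_factory=list)
    community_specs: list[CommunityMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_prob <= 1):
            raise ValueError("occupancy_prob must be in (0, 1]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["query_specs"] = [QuerySpec(**q) for q in raw.get("query_specs", [])]
        raw["community_specs"] = [
            CommunityMember(**m) for m in raw.get("community_specs", [])
        ]
        return cls(**raw)


@dataclass
class GroundTruth:
    true_tree: dendropy.Tree
    true_assignments: dict[str, tuple[str, str]]  # query -> (category, label)
    true_locus_presence: pd.DataFrame  # locus x taxon booleans
    true_depths: dict[tuple[str, str], float]  # (sample, member) -> mean depth


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int,
    birth_rate: float,
    seed: int,
    depth: float = DEFAULT_TREE_DEPTH,
    min_terminal: float = MIN_TERMINAL_BRANCH,
) -> dendropy.Tree:
    """Yule tree with ``n_taxa`` ingroup leaves plus a long-branch outgroup.

    Leaves are labeled T01..Tnn; the outgroup attaches at the root with a
    long stem so rooting is unambiguous. Ingroup branches are rescaled so
    the mean root-to-leaf path equals ``depth`` substitutions/site, and
    terminal branches are floored at ``min_terminal`` — a curated panel
    holds distinct species, never near-identical genomes, so reference
    tips are separated by at least typical interspecies divergence.
    Deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = py_substream(seed, "species-tree")
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label), 1):
        leaf.taxon.label = f"T{i:02d}"
    # the simulator stops at a speciation event, leaving zero-length tips
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length or 0.0) <= 0:
            edge.length = rng.expovariate(10.0 * birth_rate)
    def root_to_leaf(leaf: dendropy.Node) -> float:
        total, node = 0.0, leaf
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
        return total

    mean_depth = sum(root_to_leaf(lf) for lf in tree.leaf_node_iter()) / n_taxa
    scale = depth / mean_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = max(leaf.edge.length or 0.0, min_terminal)
    new_root = dendropy.Node()
    old_root = tree.seed_node
    outgroup = dendropy.Node()
    outgroup.taxon = tree.taxon_namespace.new_taxon(label=OUTGROUP_LABEL)
    tree.seed_node = new_root
    new_root.add_child(old_root)
    new_root.add_child(outgroup)
    # fixed modest stem keeps the outgroup's total divergence bounded
    old_root.edge.length = 0.1 * depth
    outgroup.edge.length = OUTGROUP_BRANCH
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# protein evolution


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length, dtype=np.uint8)


def _mutate(
    seq: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """Place Poisson(d * L) substitution events, each replacing the
    residue with one of the 19 alternatives uniformly."""
    out = seq.copy()
    n_events = rng.poisson(divergence * len(seq))
    if n_events:
        sites = rng.integers(0, len(seq), size=n_events)
        shifts = rng.integers(1, 20, size=n_events).astype(np.uint8)
        for site, shift in zip(sites, shifts):
            out[site] = (out[site] + shift) % 20
    return out


def to_residues(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def from_residues(residues: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in residues], dtype=np.uint8)


def evolve_proteins(
    tree: dendropy.Tree, n_loci: int, locus_length: int, seed: int
) -> dict[str, dict[str, np.ndarray]]:
    """Evolve ``n_loci`` loci of ``locus_length`` residues along the tree.

    Returns taxon -> locus_id -> residue-index array. Root sequences are
    uniform over the 20 residues; every branch applies the 20-state
    equal-rates substitution process, so all copies of a locus share one
    length and no alignment step is needed.
    """
    if locus_length < 20:
        raise ValueError("locus_length must be >= 20")
    rng = substream(seed, "protein-evolution")
    loci = [f"L{i:04d}" for i in range(n_loci)]
    out: dict[str, dict[str, np.ndarray]] = {}
    for locus in loci:
        root_seq = _random_protein(rng, locus_length)
        state: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_seq = state[id(node.parent_node)]
            state[id(node)] = _mutate(parent_seq, node.edge.length or 0.0, rng)
        for leaf in tree.leaf_node_iter():
            out.setdefault(leaf.taxon.label, {})[locus] = state[id(leaf)]
    return out


def apply_occupancy(
    loci: dict[str, dict[str, np.ndarray]],
    occupancy_prob: float,
    seed: int,
    outgroup: str = OUTGROUP_LABEL,
) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]]]:
    """Independently retain each (locus, taxon) cell with ``occupancy_prob``.

    The outgroup keeps every locus so the root of the tree is always
    anchored. Returns (locus x taxon boolean mask, reduced loci).
    """
    if not (0 < occupancy_prob <= 1):
        raise ValueError("occupancy_prob must be in (0, 1]")
    rng = substream(seed, "occupancy")
    taxa = sorted(loci)
    locus_ids = sorted(next(iter(loci.values())))
    mask = pd.DataFrame(True, index=locus_ids, columns=taxa)
    for taxon in taxa:
        if taxon == outgroup:
            continue
        keep = rng.random(len(locus_ids)) < occupancy_prob
        mask[taxon] = keep
    reduced = {
        taxon: {
            locus: seq
            for locus, seq in by_locus.items()
            if bool(mask.at[locus, taxon])
        }
        for taxon, by_locus in loci.items()
    }
    return mask, reduced


# ---------------------------------------------------------------------------
# query MAGs


@dataclass
class QueryMag:
    query_id: str
    proteome: dict[str, np.ndarray]  # locus -> residues (contaminant copies
    # get a ".c" suffix on the locus id)
    scaffolds: list[tuple[str, str]]  # (scaffold id, nucleotide sequence)


def back_translate(seq: np.ndarray) -> str:
    return "".join(_CODON[AMINO_ACIDS[i]] for i in seq)


def _cut_scaffolds(
    query_id: str, genome: str, rng: np.random.Generator, median_bp: float = 20_000.0
) -> list[tuple[str, str]]:
    scaffolds = []
    pos = 0
    while pos < len(genome):
        ln = int(rng.lognormal(mean=np.log(median_bp), sigma=1.0))
        ln = max(ln, 1000)
        scaffolds.append((f"{query_id}_s{len(scaffolds) + 1}", genome[pos : pos + ln]))
        pos += ln
    return scaffolds


def make_query_mag(
    panel: dict[str, dict[str, np.ndarray]],
    spec: QuerySpec,
    seed: int,
) -> QueryMag:
    """Evolve a query MAG off its reference at the requested divergence.

    A random (1 - completeness) fraction of loci is deleted; a
    ``contamination`` fraction of loci gains a second copy taken from the
    chimera partner (or the lexicographically last other taxon), giving
    duplicated markers. A chimeric query instead draws half its loci from
    each of the two parents.
    """
    if spec.reference not in panel:
        raise KeyError(f"reference {spec.reference!r} not in panel")
    rng = substream(seed, f"query:{spec.query_id}")
    ref = panel[spec.reference]
    locus_ids = sorted(ref)

    if spec.chimera_with is not None:
        if spec.chimera_with not in panel:
            raise KeyError(f"chimera partner {spec.chimera_with!r} not in panel")
        other = panel[spec.chimera_with]
        half = len(locus_ids) // 2
        proteome = {}
        for i, locus in enumerate(locus_ids):
            source = ref if i < half else other
            if locus in source:
                proteome[locus] = _mutate(source[locus], spec.divergence, rng)
    else:
        proteome = {
            locus: _mutate(ref[locus], spec.divergence, rng) for locus in locus_ids
        }

    if spec.completeness < 1.0:
        keep = rng.random(len(proteome)) < spec.completeness
        proteome = {
            locus: seq
            for (locus, seq), k in zip(sorted(proteome.items()), keep)
            if k
        }
    if spec.contamination > 0.0:
        donor_taxon = spec.chimera_with or max(t for t in panel if t != spec.reference)
        donor = panel[donor_taxon]
        for locus in sorted(proteome):
            if rng.random() < spec.contamination and locus in donor:
                proteome[f"{locus}.c"] = donor[locus].copy()

    genome = "".join(
        back_translate(proteome[locus]) for locus in sorted(proteome)
    )
    return QueryMag(spec.query_id, proteome, _cut_scaffolds(spec.query_id, genome, rng))


# ---------------------------------------------------------------------------
# depth / pileup simulation


def simulate_pileup(
    member: str,
    mean_depth: float,
    genome_length: int,
    strain_fraction: float,
    strain_divergence: float,
    seed: int,
    dispersion: float = 10.0,
) -> pd.DataFrame:
    """Per-base depth table with strain-mixture alternate alleles.

    Depth at each position is negative binomial with the given mean and
    dispersion (gamma-Poisson; larger dispersion = closer to Poisson).
    A minor strain at ``strain_fraction`` differs from the major strain
    at Bernoulli(``strain_divergence``) positions; there the alternate
    allele count is Binomial(depth, strain_fraction). Positions are
    1-based; zero-depth positions are omitted (sparse convention).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0 <= strain_fraction <= 0.5):
        raise ValueError("strain_fraction must be in [0, 0.5]")
    rng = substream(seed, f"pileup:{member}")
    p = dispersion / (dispersion + mean_depth)
    depth = rng.negative_binomial(dispersion, p, size=genome_length)
    alt = np.zeros(genome_length, dtype=np.int64)
    if strain_fraction > 0 and strain_divergence > 0:
        divergent = rng.random(genome_length) < strain_divergence
        alt[divergent] = rng.binomial(depth[divergent], strain_fraction)
    covered = depth > 0
    return pd.DataFrame(
        {
            "scaffold": member,
            "pos": np.arange(1, genome_length + 1)[covered],
            "depth": depth[covered],
            "alt_count": alt[covered],
        }
    )


def expected_alt_positions(
    mean_depth: float,
    genome_length: int,
    strain_fraction: float,
    strain_divergence: float,
    alt_min_count: int = 2,
    alt_min_fraction: float = 0.1,
    dispersion: float = 10.0,
    max_depth: int = 2000,
) -> tuple[float, float]:
    """Mean and SD of the number of positions called heterogeneous.

    Computed numerically from the stated gamma-Poisson / Bernoulli /
    binomial model and the caller's (min count, min fraction) rule, for
    use as an independent check on simulated tables.
    """
    from scipy import stats

    p = dispersion / (dispersion + mean_depth)
    depths = np.arange(0, max_depth + 1)
    w = stats.nbinom.pmf(depths, dispersion, p)
    # P(alt called | depth): alt >= alt_min_count and alt/depth >= fraction
    p_call_given_depth = np.zeros_like(w)
    for i, dep in enumerate(depths):
        if dep == 0:
            continue
        kmin = max(alt_min_count, int(np.ceil(alt_min_fraction * dep)))
        p_call_given_depth[i] = stats.binom.sf(kmin - 1, dep, strain_fraction)
    p_call = strain_divergence * float(np.sum(w * p_call_given_depth))
    mean = genome_length * p_call
    sd = float(np.sqrt(genome_length * p_call * (1 - p_call)))
    return mean, sd


# ---------------------------------------------------------------------------
# whole-scenario generation


# beyond this divergence a query emulates a broken (misassembled or
# error-rich) genome: its branch is long relative to every reference
REJECT_DIVERGENCE = 0.3


def _truth_category(spec: QuerySpec) -> tuple[str, str]:
    """Intended classification for a query, given how it was built."""
    from .classify import ClassifyParams

    params = ClassifyParams()
    if spec.chimera_with is not None or spec.divergence >= REJECT_DIVERGENCE:
        return "rejected_long_branch", ""
    if spec.divergence <= params.t_conspecific:
        return "conspecific", spec.reference
    if spec.divergence <= params.t_genus:
        return "provisional_species", spec.reference
    return "family_level", ""


def generate_all(config: SimConfig, outdir: str | Path | None = None) -> dict:
    """Run every generator from one configuration.

    Returns a dict with the tree, panel/query proteomes, occupancy mask,
    query MAGs, per-member depth tables, and the GroundTruth record. If
    ``outdir`` is given, writes the standard file layout (FASTA
    proteomes and bins, Newick tree, TSV tables, config echo).
    """
    tree = simulate_species_tree(config.n_ref_taxa, config.birth_rate, config.seed)
    panel = evolve_proteins(tree, config.n_loci, config.locus_length, config.seed)
    mask, reduced = apply_occupancy(panel, config.occupancy_prob, config.seed)
    queries = {
        spec.query_id: make_query_mag(panel, spec, config.seed)
        for spec in config.query_specs
    }
    pileups = {
        (m.sample, m.member): simulate_pileup(
            m.member,
            m.mean_depth,
            m.genome_length,
            m.strain_fraction,
            m.strain_divergence,
            config.seed,
        )
        for m in config.community_specs
    }
    truth = GroundTruth(
        true_tree=tree,
        true_assignments={
            spec.query_id: _truth_category(spec) for spec in config.query_specs
        },
        true_locus_presence=mask,
        true_depths={
            (m.sample, m.member): m.mean_depth for m in config.community_specs
        },
    )
    result = {
        "tree": tree,
        "panel": panel,
        "occupancy_mask": mask,
        "panel_reduced": reduced,
        "queries": queries,
        "pileups": pileups,
        "truth": truth,
    }
    if outdir is not None:
        _write_all(config, result, Path(outdir))
    return result


def _write_all(config: SimConfig, result: dict, outdir: Path) -> None:
    from .treekit import write_newick

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "proteomes").mkdir(exist_ok=True)
    for taxon, by_locus in result["panel_reduced"].items():
        with open(outdir / "proteomes" / f"{taxon}.fasta", "w") as fh:
            for locus in sorted(by_locus):
                fh.write(f">{taxon}|{locus}\n{to_residues(by_locus[locus])}\n")
    (outdir / "bins").mkdir(exist_ok=True)
    for qid, mag in result["queries"].items():
        with open(outdir / "bins" / f"{qid}.fasta", "w") as fh:
            for sid, seq in mag.scaffolds:
                fh.write(f">{sid}\n{seq}\n")
        with open(outdir / "bins" / f"{qid}.proteins.fasta", "w") as fh:
            for locus in sorted(mag.proteome):
                fh.write(f">{qid}|{locus}\n{to_residues(mag.proteome[locus])}\n")
    write_newick(result["tree"], outdir / "true_tree.nwk")
    result["occupancy_mask"].to_csv(outdir / "true_locus_presence.tsv", sep="\t")
    truth = result["truth"]
    pd.DataFrame(
        [
            {"query_id": q, "category": c, "label": lab}
            for q, (c, lab) in truth.true_assignments.items()
        ]
    ).to_csv(outdir / "true_assignments.tsv", sep="\t", index=False)
    depth_rows = []
    for (sample, member), table in result["pileups"].items():
        t = table.copy()
        t.insert(0, "sample", sample)
        depth_rows.append(t)
    if depth_rows:
        pd.concat(depth_rows).to_csv(outdir / "depth_tables.tsv", sep="\t", index=False)
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(
            {
                "seed": config.seed,
                "n_ref_taxa": config.n_ref_taxa,
                "n_loci": config.n_loci,
                "locus_length": config.locus_length,
                "birth_rate": config.birth_rate,
                "occupancy_prob": config.occupancy_prob,
                "query_specs": [vars(q) for q in config.query_specs],
                "community_specs": [vars(m) for m in config.community_specs],
            }
        )
    )
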