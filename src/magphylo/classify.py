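"""Reference-anchored species assignment of query MAGs from a phylogeny.

Given a rooted, support-annotated tree containing reference genomes and
query MAGs, each query is classified by a fixed decision cascade on
patristic-distance evidence:

1. anomalously long terminal branches are rejected outright (chimera /
   misassembly guard);
2. the smallest clade around the query with stem support at or above
   ``min_support`` is located;
3. evidence is extracted: nearest reference (minimum patristic leaf
   distance), number of reference species co-clustered or attached as
   the immediate sister group, intra-clade distances among co-clustered
   queries, and the clade's stem support;
4. the cascade maps evidence to a category: conspecific with the nearest
   reference, provisional species (single near reference but beyond the
   conspecific threshold), novel species within a genus (several equally
   near references), family-level fallback (too distant, or the nearest
   genus is flagged non-monophyletic, as for *Candida* sensu lato), or
   unplaced when support is lacking.

Distance thresholds default to 0.02 (conspecific) and 0.08 (same genus)
substitutions per site.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .taxonomy import Taxonomy
from .treekit import edge_support, patristic, support_value

CONSPECIFIC = "conspecific"
PROVISIONAL = "provisional_species"
NOVEL_IN_GENUS = "novel_species_in_genus"
FAMILY_LEVEL = "family_level"
REJECTED = "rejected_long_branch"
UNPLACED = "unplaced"

CATEGORIES = (CONSPECIFIC, PROVISIONAL, NOVEL_IN_GENUS, FAMILY_LEVEL, REJECTED, UNPLACED)


@dataclass(frozen=True)
class ClassifyParams:
    min_support: int = 95
    t_conspecific: float = 0.02
    t_genus: float = 0.08
    long_branch_factor: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.t_conspecific < self.t_genus):
            raise ValueError("need 0 < t_conspecific < t_genus")
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support must be in [0, 100]")


@dataclass
class Evidence:
    query_id: str
    nearest_ref: str
    d_nearest: float
    n_refs_equally_near: int
    intra_clade_range: tuple[float, float] | None
    clade_support: int


@dataclass
class Assignment:
    query_id: str
    category: str
    rank: str
    label: str
    genus_label: str  # label used when tallying at genus rank
    evidence: Evidence | None = None


# ---------------------------------------------------------------------------
# tree-side operations


def long_branch_filter(
    tree: dendropy.Tree, queries: set[str], factor: float = 5.0
) -> list[str]:
    """Queries whose terminal branch exceeds ``factor`` x the median
    reference terminal branch length."""
    ref_lengths, query_leaf = [], {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in queries:
            query_leaf[label] = leaf
        else:
            ref_lengths.append(leaf.edge.length or 0.0)
    if not ref_lengths:
        raise ValueError("tree contains no reference leaves")
    cutoff = factor * statistics.median(ref_lengths)
    return sorted(
        q for q, leaf in query_leaf.items() if (leaf.edge.length or 0.0) > cutoff
    )


def supported_clade(
    tree: dendropy.Tree, query: str, min_support: int
) -> tuple[dendropy.Node, int]:
    """Smallest clade containing the query with stem support >= threshold.

    Walks rootward from the query's parent; returns (clade root node,
    stem support). Reaching the tree root returns the whole tree with
    support 0 (no supported clade exists).
    """
    leaf = next(
        (lf for lf in tree.leaf_node_iter() if lf.taxon.label == query), None
    )
    if leaf is None:
        raise KeyError(f"query {query!r} is not a leaf")
    node = leaf.parent_node
    while node is not None and node.parent_node is not None:
        sup = edge_support(node)
        if sup >= min_support:
            return node, sup
        node = node.parent_node
    return tree.seed_node, 0


def extract_evidence(
    tree: dendropy.Tree,
    query: str,
    clade: dendropy.Node,
    queries: set[str],
    clade_support: int | None = None,
) -> Evidence:
    """Distance and clade-composition evidence for one query.

    Reference leaves are all leaves that are not queries. The nearest
    reference is found tree-wide by minimum patristic distance (ties
    break lexicographically); co-clustered reference species are counted
    inside the clade, falling back to the immediate sister group when
    the clade holds queries only.
    """
    all_leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    refs = [lb for lb in all_leaves if lb not in queries]
    if not refs:
        raise ValueError("tree contains no reference leaves")

    dists = {ref: patristic(tree, query, ref) for ref in refs}
    nearest = min(sorted(dists), key=lambda r: dists[r])

    clade_leaves = [lf.taxon.label for lf in clade.leaf_iter()]
    refs_in_clade = sorted(set(lb for lb in clade_leaves if lb not in queries))
    if not refs_in_clade and clade.parent_node is not None:
        sister_leaves = [
            lf.taxon.label
            for child in clade.parent_node.child_nodes()
            if child is not clade
            for lf in child.leaf_iter()
        ]
        refs_in_clade = sorted(set(lb for lb in sister_leaves if lb not in queries))

    co_queries = [lb for lb in clade_leaves if lb in queries and lb != query]
    intra = None
    if co_queries:
        pair_d = [patristic(tree, query, other) for other in co_queries]
        intra = (min(pair_d), max(pair_d))

    if clade_support is None:
        clade_support = 0 if clade.parent_node is None else edge_support(clade)
    return Evidence(
        query_id=query,
        nearest_ref=nearest,
        d_nearest=dists[nearest],
        n_refs_equally_near=len(refs_in_clade),
        intra_clade_range=intra,
        clade_support=clade_support,
    )


# ---------------------------------------------------------------------------
# the decision cascade


def _rank_labels(taxonomy: Taxonomy, species: str) -> dict[str, str]:
    labels = {}
    for rank in ("species", "genus", "family"):
        node = taxonomy.ancestor_at(species, rank)
        if node is None:
            raise ValueError(f"taxon {species!r} lacks an ancestor at rank {rank}")
        labels[rank] = node
    return labels


def classify_query(
    evidence: Evidence, taxonomy: Taxonomy, params: ClassifyParams
) -> Assignment:
    """Map one evidence record to a category (first matching rule wins)."""
    ranks = _rank_labels(taxonomy, evidence.nearest_ref)
    genus, family = ranks["genus"], ranks["family"]

    if evidence.clade_support < params.min_support:
        return Assignment(
            evidence.query_id, UNPLACED, "genus", genus, genus, evidence
        )
    if genus in taxonomy.unstable:
        return Assignment(
            evidence.query_id, FAMILY_LEVEL, "family", family,
            f"{family} sp.", evidence,
        )
    if evidence.n_refs_equally_near == 1 and evidence.d_nearest <= params.t_conspecific:
        return Assignment(
            evidence.query_id, CONSPECIFIC, "species", ranks["species"],
            genus, evidence,
        )
    if evidence.n_refs_equally_near == 1 and evidence.d_nearest <= params.t_genus:
        return Assignment(
            evidence.query_id, PROVISIONAL, "species", ranks["species"],
            genus, evidence,
        )
    if evidence.d_nearest <= params.t_genus and evidence.n_refs_equally_near > 1:
        return Assignment(
            evidence.query_id, NOVEL_IN_GENUS, "genus", genus, genus, evidence
        )
    return Assignment(
        evidence.query_id, FAMILY_LEVEL, "family", family,
        f"{family} sp.", evidence,
    )


def sample_of(query_id: str) -> str:
    """Sample id parsed from a query-id prefix (e.g. CF02scaffolds_bin_4
    -> CF02)."""
    m = re.match(r"([A-Za-z]+\d+)", query_id)
    return m.group(1) if m else query_id


def classify_all(
    tree: dendropy.Tree,
    queries: list[str],
    taxonomy: Taxonomy,
    params: ClassifyParams | None = None,
) -> tuple[list[Assignment], pd.DataFrame]:
    """Long-branch QC then per-query cascade; returns assignments and a
    per-category tally table."""
    params = params or ClassifyParams()
    if len(set(queries)) != len(queries):
        raise ValueError("duplicate query ids")
    qset = set(queries)
    flagged = set(long_branch_filter(tree, qset, params.long_branch_factor))
    assignments = []
    for query in queries:
        if query in flagged:
            assignments.append(Assignment(query, REJECTED, "none", "", ""))
            continue
        clade, sup = supported_clade(tree, query, params.min_support)
        ev = extract_evidence(tree, query, clade, qset, clade_support=sup)
        assignments.append(classify_query(ev, taxonomy, params))
    return assignments, tally(assignments)


def tally(assignments: list[Assignment]) -> pd.DataFrame:
    rows = [
        {
            "query_id": a.query_id,
            "sample": sample_of(a.query_id),
            "category": a.category,
            "label": a.label,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evidence-table interface (bypasses tree parsing)


def classify_from_evidence(
    table: pd.DataFrame, taxonomy: Taxonomy, params: ClassifyParams | None = None
) -> list[Assignment]:
    """Classify from a precomputed evidence table.

    Columns: query_id, nearest_ref, d_nearest, n_refs_equally_near,
    clade_support, and optional intra_min / intra_max.
    """
    params = params or ClassifyParams()
    out = []
    for row in table.itertuples(index=False):
        intra = None
        if hasattr(row, "intra_min") and pd.notna(row.intra_min):
            intra = (float(row.intra_min), float(row.intra_max))
        ev = Evidence(
            query_id=str(row.query_id),
            nearest_ref=str(row.nearest_ref),
            d_nearest=float(row.d_nearest),
            n_refs_equally_near=int(row.n_refs_equally_near),
            intra_clade_range=intra,
            clade_support=int(row.clade_support),
        )
        out.append(classify_query(ev, taxonomy, params))
    return out


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        ev = a.evidence
        rows.append(
            {
                "query_id": a.query_id,
                "sample": sample_of(a.query_id),
                "category": a.category,
                "rank": a.rank,
                "label": a.label,
                "d_nearest": ev.d_nearest if ev else float("nan"),
                "nearest_ref": ev.nearest_ref if ev else "",
                "support": ev.clade_support if ev else -1,
            }
        )
    return pd.DataFrame(rows)


def write_assignments(assignments: list[Assignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)
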