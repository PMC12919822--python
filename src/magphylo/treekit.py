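"""Distance-based tree inference and patristic-distance queries.

Distances come from a Poisson-corrected 20-state model applied to the
supermatrix with pairwise deletion of gapped columns; trees are built by
neighbor joining with deterministic tie-breaks, given bootstrap supports
by nonparametric column resampling, and rooted on a designated outgroup.
Externally inferred trees (e.g. IQ-TREE maximum likelihood output) can be
imported from Newick; internal-node labels are read as bootstrap supports
(for "a/b"-style labels the last field is used).

Branch lengths are in expected substitutions per site throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rng import substream
from .supermatrix import SuperMatrix

_GAP_BYTE = ord("-")
_MAX_P = 19.0 / 20.0


class UndefinedDistanceError(ValueError):
    """No comparable (mutually ungapped) sites between two rows."""


class SaturatedDistanceError(ValueError):
    """Observed mismatch fraction at or beyond the model's ceiling (19/20)."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    comparable: np.ndarray | None = None  # per-pair ungapped site counts

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def correct_distance(p: float) -> float:
    """Poisson correction for a 20-state equal-rates model.

    Inverts E[p] = (19/20) (1 - exp(-20 d / 19)); monotone in p and -> 0
    as p -> 0.
    """
    if p >= _MAX_P:
        raise SaturatedDistanceError(f"p = {p:.4f} >= 19/20; distance saturated")
    return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)


def _encode_rows(matrix: SuperMatrix) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8) for t in matrix.taxa]
    )


def protein_distance(
    matrix: SuperMatrix, taxon_a: str, taxon_b: str
) -> tuple[float, int]:
    """Corrected distance and comparable-site count for one taxon pair.

    Columns where either row is gapped are excluded (pairwise deletion).
    """
    a = np.frombuffer(matrix.rows[taxon_a].encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(matrix.rows[taxon_b].encode("ascii"), dtype=np.uint8)
    mask = (a != _GAP_BYTE) & (b != _GAP_BYTE)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between {taxon_a!r} and {taxon_b!r}"
        )
    p = float(((a != b) & mask).sum()) / n
    return correct_distance(p), n


def distance_matrix(matrix: SuperMatrix) -> DistanceMatrix:
    """All-pairs corrected distances from a supermatrix."""
    enc = _encode_rows(matrix)
    return _distances_from_encoded(matrix.taxa, enc)


def _distances_from_encoded(taxa: list[str], enc: np.ndarray) -> DistanceMatrix:
    n = len(taxa)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    ungapped = enc != _GAP_BYTE
    for i in range(n):
        for j in range(i + 1, n):
            mask = ungapped[i] & ungapped[j]
            nsites = int(mask.sum())
            if nsites == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            p = float(((enc[i] != enc[j]) & mask).sum()) / nsites
            d[i, j] = d[j, i] = correct_distance(p)
            comp[i, j] = comp[j, i] = nsites
    return DistanceMatrix(list(taxa), d, comp)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion break to the lowest
    (row, column) index pair. Negative branch-length estimates are
    clamped to zero with the deficit moved onto the sister branch, so
    patristic distances stay a valid metric. Returns an unrooted tree
    (trifurcating seed node).
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label=name)
        nodes.append(node)

    d = dm.d.astype(float).copy()
    active = list(range(n0))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    center = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, supports, bootstrap


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, object]:
    """Rooting-invariant bipartition keys for internal edges.

    Key = frozenset of the two leaf-label sides. Trivial bipartitions
    (single leaf / whole set) are excluded.
    """
    all_leaves = frozenset(leaf_labels(tree))
    out: dict[frozenset, object] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) <= 1 or len(other) <= 1:
            continue
        out[frozenset((side, other))] = node
    return out


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric bipartition difference."""
    ba, bb = set(_bipartitions(tree_a)), set(_bipartitions(tree_b))
    return len(ba ^ bb)


def support_value(label: str | None) -> int | None:
    """Parse a support integer from an internal-node label.

    "95" -> 95; "0.99/87" -> 87 (last "/"-field wins); None/empty -> None.
    """
    if label is None or label == "":
        return None
    field = str(label).split("/")[-1]
    try:
        return round(float(field))
    except ValueError:
        return None


def edge_support(node: dendropy.Node) -> int:
    """Support of the edge above a node; terminal edges count as 100."""
    if node.is_leaf():
        return 100
    val = support_value(node.label)
    return 100 if val is None and node.parent_node is None else (val if val is not None else 0)


def bootstrap_support(
    matrix: SuperMatrix, n_reps: int = 200, seed: int = 0
) -> dendropy.Tree:
    """NJ tree with supports from nonparametric column resampling.

    Each replicate resamples supermatrix columns with replacement,
    recomputes distances and the NJ tree; an internal edge's support is
    the rounded percentage of replicates containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = _encode_rows(matrix)
    main = neighbor_joining(_distances_from_encoded(matrix.taxa, enc))
    rng = substream(seed, "bootstrap")
    ncol = enc.shape[1]
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = neighbor_joining(
            _distances_from_encoded(matrix.taxa, enc[:, cols])
        )
        for key in _bipartitions(rep_tree):
            counts[key] = counts.get(key, 0) + 1
    for key, node in _bipartitions(main).items():
        node.label = str(round(100.0 * counts.get(key, 0) / n_reps))
    return main


def annotate_supports(
    tree: dendropy.Tree, supports: dict[frozenset, int]
) -> None:
    """Attach supports to whichever internal edges carry the bipartitions."""
    for key, node in _bipartitions(tree).items():
        if key in supports:
            node.label = str(supports[key])


def collect_supports(tree: dendropy.Tree) -> dict[frozenset, int]:
    return {
        key: val
        for key, node in _bipartitions(tree).items()
        if (val := support_value(node.label)) is not None
    }


# ---------------------------------------------------------------------------
# rooting and patristic distances


def root_tree(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's terminal edge.

    Supports are re-attached by bipartition, so rerooting never migrates
    a support value onto a different split.
    """
    supports = collect_supports(tree)
    leaf = next(
        (lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup_label),
        None,
    )
    if leaf is None:
        raise KeyError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    half = (leaf.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(leaf.edge, length1=half, length2=half)
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
    annotate_supports(tree, supports)
    return tree


def patristic(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    found = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in (leaf_a, leaf_b):
            found[leaf.taxon.label] = leaf
    for label in (leaf_a, leaf_b):
        if label not in found:
            raise KeyError(f"leaf {label!r} not in tree")
    if leaf_a == leaf_b:
        return 0.0

    def path_to_root(node):
        path = {}
        dist = 0.0
        while node is not None:
            path[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        return path

    pa = path_to_root(found[leaf_a])
    node, dist_b = found[leaf_b], 0.0
    while node is not None:
        if id(node) in pa:
            return pa[id(node)] + dist_b
        dist_b += node.edge.length or 0.0
        node = node.parent_node
    raise RuntimeError("leaves share no ancestor; malformed tree")


def patristic_table(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs patristic distances as a labeled DataFrame."""
    labels = sorted(leaf_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist = pdm.patristic_distance(by_label[a], by_label[b])
            out.loc[a, b] = out.loc[b, a] = dist
    return out


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal labels retained as support labels."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
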