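import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magphylo.supermatrix import LocusAlignment, concatenate
from magphylo.synthgen import simulate_species_tree
from magphylo.treekit import (
    DistanceMatrix,
    SaturatedDistanceError,
    UndefinedDistanceError,
    bootstrap_support,
    correct_distance,
    distance_matrix,
    edge_support,
    leaf_labels,
    neighbor_joining,
    patristic,
    patristic_table,
    protein_distance,
    read_newick,
    rf_distance,
    root_tree,
    support_value,
    write_newick,
)


# ---------------------------------------------------------------------------
# distance correction


def test_correct_distance_closed_form():
    # p = 0.05: d = -(19/20) ln(1 - 1/19) = (19/20) ln(19/18)
    assert correct_distance(0.05) == pytest.approx(0.95 * math.log(19 / 18))
    assert correct_distance(0.0) == 0.0


def test_correct_distance_monotone():
    ps = np.linspace(0, 0.9, 50)
    ds = [correct_distance(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    assert all(d >= p for p, d in zip(ps, ds))  # correction only inflates


def test_correct_distance_saturation():
    with pytest.raises(SaturatedDistanceError):
        correct_distance(19 / 20)


def test_protein_distance_pairwise_deletion():
    sm = concatenate(
        [LocusAlignment("L1", {"TA": "AAAA", "TB": "AAAC"}), LocusAlignment("L2", {"TA": "DDDD"})],
        ["TA", "TB"],
    )
    d, n = protein_distance(sm, "TA", "TB")
    assert n == 4  # the gapped L2 block is excluded
    assert d == pytest.approx(correct_distance(0.25))


def test_protein_distance_no_overlap_raises():
    sm = concatenate(
        [LocusAlignment("L1", {"TA": "AAAA"}), LocusAlignment("L2", {"TB": "CCCC"})],
        ["TA", "TB"],
    )
    with pytest.raises(UndefinedDistanceError):
        protein_distance(sm, "TA", "TB")


def test_distance_matrix_symmetric_zero_diag():
    sm = concatenate(
        [LocusAlignment("L1", {"TA": "ACDE", "TB": "ACDF", "TC": "AKDE"})],
        ["TA", "TB", "TC"],
    )
    dm = distance_matrix(sm)
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert dm.d[0, 1] == pytest.approx(correct_distance(0.25))


# ---------------------------------------------------------------------------
# neighbor joining


def _patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = patristic(tree, taxa[i], taxa[j])
    return out


def test_nj_three_taxon_closed_form():
    taxa = ["A", "B", "C"]
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    # three-point formulas: a=1, b=2, c=3
    assert patristic(tree, "A", "B") == pytest.approx(3.0)
    assert patristic(tree, "A", "C") == pytest.approx(4.0)
    assert patristic(tree, "B", "C") == pytest.approx(5.0)


def test_nj_four_taxon_additive_recovery():
    # ((A:1,B:2):0.5,(C:3,D:4)) with internal edge 0.5
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0.0, 3.0, 4.5, 5.5],
            [3.0, 0.0, 5.5, 6.5],
            [4.5, 5.5, 0.0, 7.0],
            [5.5, 6.5, 7.0, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    assert np.allclose(_patristic_matrix(tree, taxa), d)


def test_nj_recovers_random_additive_matrices():
    for seed in range(5):
        true = simulate_species_tree(8, 1.0, seed)
        taxa = sorted(leaf_labels(true))
        d = _patristic_matrix(true, taxa)
        est = neighbor_joining(DistanceMatrix(taxa, d))
        assert rf_distance(est, true) == 0
        assert np.allclose(_patristic_matrix(est, taxa), d, atol=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
    bad = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A", "B", "C"], np.full((3, 3), np.inf)))
    del bad


def test_nj_branch_lengths_nonnegative():
    # non-additive noisy matrix still yields a valid metric tree
    rng = np.random.default_rng(11)
    n = 6
    base = rng.uniform(0.2, 1.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = neighbor_joining(DistanceMatrix([f"T{i}" for i in range(n)], d))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            assert node.edge.length >= 0


# ---------------------------------------------------------------------------
# supports, rooting, RF


def test_support_value_parsing():
    assert support_value("95") == 95
    assert support_value("0.99/87") == 87
    assert support_value("99.6") == 100
    assert support_value(None) is None
    assert support_value("") is None
    assert support_value("abc") is None


def test_rf_distance_identical_and_different():
    a = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    b = read_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
    assert rf_distance(a, a) == 0
    # each tree carries 2 non-trivial bipartitions, none shared -> 4
    assert rf_distance(a, b) == 4


def test_newick_round_trip(tmp_path):
    text = "((A:1.5,B:2.25)90:0.5,(C:3,D:4)75:0.125,E:1);"
    tree = read_newick(text)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert rf_distance(tree, back) == 0
    for x, y in zip(sorted(leaf_labels(tree)), sorted(leaf_labels(back))):
        assert x == y
    assert patristic(back, "A", "B") == pytest.approx(3.75)


def test_rooting_preserves_supports_and_distances():
    tree = read_newick("((A:1,B:1)90:1,(C:1,OG:5)80:1,E:1);")
    before = {
        pair: patristic(tree, *pair)
        for pair in [("A", "B"), ("A", "C"), ("B", "E"), ("A", "OG")]
    }
    rooted = root_tree(tree, "OG")
    for pair, val in before.items():
        assert patristic(rooted, *pair) == pytest.approx(val)
    # the A|B split still carries support 90 after rerooting
    node_ab = next(
        nd
        for nd in rooted.preorder_node_iter()
        if not nd.is_leaf()
        and {lf.taxon.label for lf in nd.leaf_iter()} == {"A", "B"}
    )
    assert edge_support(node_ab) == 90


def test_root_tree_missing_outgroup():
    with pytest.raises(KeyError):
        root_tree(read_newick("((A:1,B:1):1,C:1,D:1);"), "ZZ")


def test_patristic_matches_dendropy():
    tree = simulate_species_tree(7, 1.0, 5)
    table = patristic_table(tree)
    labels = sorted(leaf_labels(tree))
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert patristic(tree, a, b) == pytest.approx(table.loc[a, b])


@given(seed=st.integers(0, 50))
def test_patristic_metric_property(seed):
    tree = simulate_species_tree(6, 1.0, seed)
    labels = sorted(leaf_labels(tree))
    a, b, c = labels[0], labels[2], labels[4]
    dab = patristic(tree, a, b)
    dbc = patristic(tree, b, c)
    dac = patristic(tree, a, c)
    assert dab >= 0 and patristic(tree, a, a) == 0.0
    assert dac <= dab + dbc + 1e-12


# ---------------------------------------------------------------------------
# bootstrap


def _signal_matrix():
    # a constant block keeps every pairwise mismatch fraction below 19/20
    shared = "H" * 30
    rows = {
        "TA": "AAAAAAAAAA" + "CCCCCCCCCC" + shared,
        "TB": "AAAAAAAAAA" + "DDDDDDDDDD" + shared,
        "TC": "EEEEEEEEEE" + "CCCCCCCCCC" + shared,
        "TD": "EEEEEEEEEE" + "DDDDDDDDDD" + shared,
        "TE": "FFFFFFFFFF" + "GGGGGGGGGG" + shared,
    }
    return concatenate(
        [LocusAlignment("L1", rows)], ["TA", "TB", "TC", "TD", "TE"]
    )


def test_bootstrap_deterministic_and_bounded():
    sm = _signal_matrix()
    t1 = bootstrap_support(sm, n_reps=25, seed=3)
    t2 = bootstrap_support(sm, n_reps=25, seed=3)
    assert write_newick(t1) == write_newick(t2)
    for node in t1.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            assert 0 <= int(node.label) <= 100


def test_bootstrap_validation():
    with pytest.raises(ValueError):
        bootstrap_support(_signal_matrix(), n_reps=0)
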