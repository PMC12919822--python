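import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from magphylo.classify import (
    CONSPECIFIC,
    FAMILY_LEVEL,
    NOVEL_IN_GENUS,
    PROVISIONAL,
    REJECTED,
    UNPLACED,
    ClassifyParams,
    Evidence,
    classify_all,
    classify_query,
    extract_evidence,
    long_branch_filter,
    sample_of,
    supported_clade,
)
from magphylo.treekit import read_newick


def _ev(d, n_refs=1, support=100, nearest="Pichia kluyveri", qid="q"):
    return Evidence(qid, nearest, d, n_refs, None, support)


def test_params_validation():
    with pytest.raises(ValueError):
        ClassifyParams(t_conspecific=0.1, t_genus=0.05)
    with pytest.raises(ValueError):
        ClassifyParams(min_support=150)


def test_cascade_printed_examples(coffee_tax):
    p = ClassifyParams()
    a = classify_query(_ev(0.0070), coffee_tax, p)
    assert (a.category, a.label) == (CONSPECIFIC, "Pichia kluyveri")

    a = classify_query(_ev(0.032, n_refs=4, nearest="Hanseniaspora uvarum"), coffee_tax, p)
    assert (a.category, a.label) == (NOVEL_IN_GENUS, "Hanseniaspora")

    a = classify_query(_ev(0.0731, nearest="Kurtzmaniella quercitrusa"), coffee_tax, p)
    assert (a.category, a.label) == (PROVISIONAL, "Kurtzmaniella quercitrusa")

    a = classify_query(_ev(0.1082, nearest="Candida oleophila"), coffee_tax, p)
    assert (a.category, a.label) == (FAMILY_LEVEL, "Debaryomycetaceae")

    # unstable genus wins even at small distance
    a = classify_query(_ev(0.0386, nearest="Candida corydali"), coffee_tax, p)
    assert (a.category, a.label) == (FAMILY_LEVEL, "Debaryomycetaceae")


def test_low_support_unplaced(coffee_tax):
    a = classify_query(_ev(0.001, support=80), coffee_tax, ClassifyParams())
    assert a.category == UNPLACED
    assert a.label == "Pichia"


def test_cascade_is_total(coffee_tax):
    for d in (0.0, 0.02, 0.05, 0.08, 0.3):
        for n in (1, 2, 5):
            for s in (0, 95, 100):
                a = classify_query(_ev(d, n, s), coffee_tax, ClassifyParams())
                assert a.category in (
                    CONSPECIFIC, PROVISIONAL, NOVEL_IN_GENUS, FAMILY_LEVEL, UNPLACED,
                )


@given(
    d_lo=st.floats(0.0, 0.2), d_hi=st.floats(0.0, 0.2),
    n_refs=st.sampled_from([1, 2, 4]),
)
def test_monotonicity_in_distance(coffee_tax, d_lo, d_hi, n_refs):
    """Increasing d_nearest never moves a call to a finer rank."""
    fineness = {CONSPECIFIC: 0, PROVISIONAL: 1, NOVEL_IN_GENUS: 2, FAMILY_LEVEL: 3}
    lo, hi = min(d_lo, d_hi), max(d_lo, d_hi)
    p = ClassifyParams()
    a = classify_query(_ev(lo, n_refs), coffee_tax, p)
    b = classify_query(_ev(hi, n_refs), coffee_tax, p)
    assert fineness[b.category] >= fineness[a.category]


def test_threshold_boundaries(coffee_tax):
    p = ClassifyParams()
    assert classify_query(_ev(0.02), coffee_tax, p).category == CONSPECIFIC
    assert classify_query(_ev(0.0200001), coffee_tax, p).category == PROVISIONAL
    assert classify_query(_ev(0.08), coffee_tax, p).category == PROVISIONAL
    assert classify_query(_ev(0.0800001), coffee_tax, p).category == FAMILY_LEVEL


def test_sample_of():
    assert sample_of("CF02_bin_1") == "CF02"
    assert sample_of("CF02scaffolds_bin_4") == "CF02"
    assert sample_of("CF14scaffolds_bin_31") == "CF14"
    assert sample_of("weird") == "weird"


# ---------------------------------------------------------------------------
# tree-side operations on a hand-built tree

TREE = "(((Q1:0.01,RefA:0.01)99:0.02,RefB:0.03)90:0.1,(RefC:0.05,RefD:0.05)100:0.1,RefE:0.2);"


def test_long_branch_filter():
    text = "((Q1:0.9,RefA:0.05)90:0.05,(RefB:0.05,RefC:0.05)90:0.05,RefD:0.05);"
    tree = read_newick(text)
    # median ref terminal = 0.05; cutoff 0.25 < 0.9
    assert long_branch_filter(tree, {"Q1"}) == ["Q1"]
    # a normal-length query passes
    tree2 = read_newick(TREE)
    assert long_branch_filter(tree2, {"Q1"}) == []


def test_long_branch_filter_no_refs():
    tree = read_newick("(Q1:1,Q2:1,Q3:1);")
    with pytest.raises(ValueError):
        long_branch_filter(tree, {"Q1", "Q2", "Q3"})


def test_supported_clade_walks_rootward():
    tree = read_newick(TREE)
    clade, sup = supported_clade(tree, "Q1", min_support=95)
    assert sup == 99
    assert {lf.taxon.label for lf in clade.leaf_iter()} == {"Q1", "RefA"}
    # a stricter threshold skips the 99 node and the 90 node -> root, support 0
    clade, sup = supported_clade(tree, "Q1", min_support=100)
    assert sup == 0
    assert clade is tree.seed_node


def test_supported_clade_missing_query():
    with pytest.raises(KeyError):
        supported_clade(read_newick(TREE), "nope", 95)


def test_extract_evidence_nearest_and_clade():
    tree = read_newick(TREE)
    clade, sup = supported_clade(tree, "Q1", 95)
    ev = extract_evidence(tree, "Q1", clade, {"Q1"}, clade_support=sup)
    assert ev.nearest_ref == "RefA"
    assert ev.d_nearest == pytest.approx(0.02)
    assert ev.n_refs_equally_near == 1
    assert ev.clade_support == 99
    assert ev.intra_clade_range is None


def test_extract_evidence_sister_fallback():
    # query-only clade: references counted from the immediate sister group
    text = "(((Q1:0.01,Q2:0.01)99:0.02,(RefA:0.01,RefB:0.01)99:0.02)95:0.1,RefC:0.1,RefD:0.1);"
    tree = read_newick(text)
    clade, sup = supported_clade(tree, "Q1", 95)
    ev = extract_evidence(tree, "Q1", clade, {"Q1", "Q2"}, clade_support=sup)
    assert ev.n_refs_equally_near == 2  # RefA and RefB from the sister group
    assert ev.intra_clade_range == (
        pytest.approx(0.02),
        pytest.approx(0.02),
    )  # Q1-Q2 patristic


def test_classify_all_rejects_duplicates(coffee_tax):
    tree = read_newick(TREE)
    with pytest.raises(ValueError):
        classify_all(tree, ["Q1", "Q1"], coffee_tax)


def test_classify_all_empty_queries(coffee_tax):
    assignments, tally = classify_all(read_newick(TREE), [], coffee_tax)
    assert assignments == []
    assert len(tally) == 0


def test_classify_all_long_branch_rejected(coffee_tax):
    text = "((Q1:0.9,RefA:0.05)90:0.05,(RefB:0.05,RefC:0.05)90:0.05,RefD:0.05);"
    tree = read_newick(text)
    tax = coffee_tax  # labels unused for rejected queries
    assignments, _ = classify_all(tree, ["Q1"], tax)
    assert assignments[0].category == REJECTED


def test_permutation_invariance(coffee_evidence, coffee_tax):
    from magphylo.classify import classify_from_evidence

    fwd = classify_from_evidence(coffee_evidence, coffee_tax)
    rev = classify_from_evidence(
        coffee_evidence.iloc[::-1].reset_index(drop=True), coffee_tax
    )
    by_id_fwd = {a.query_id: (a.category, a.label) for a in fwd}
    by_id_rev = {a.query_id: (a.category, a.label) for a in rev}
    assert by_id_fwd == by_id_rev
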