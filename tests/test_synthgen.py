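import numpy as np
import pytest

from magphylo.synthgen import (
    AMINO_ACIDS,
    MIN_TERMINAL_BRANCH,
    OUTGROUP_BRANCH,
    OUTGROUP_LABEL,
    CommunityMember,
    QuerySpec,
    SimConfig,
    apply_occupancy,
    back_translate,
    evolve_proteins,
    expected_alt_positions,
    generate_all,
    make_query_mag,
    simulate_pileup,
    simulate_species_tree,
    to_residues,
)
from magphylo.treekit import leaf_labels, patristic, write_newick


def test_spec_validation():
    with pytest.raises(ValueError):
        QuerySpec("q", "T01", -0.1)
    with pytest.raises(ValueError):
        QuerySpec("q", "T01", 0.1, completeness=0.0)
    with pytest.raises(ValueError):
        SimConfig(occupancy_prob=0.0)
    with pytest.raises(ValueError):
        SimConfig(birth_rate=0.0)


def test_species_tree_shape():
    tree = simulate_species_tree(10, 1.0, 42)
    labels = leaf_labels(tree)
    assert labels == {f"T{i:02d}" for i in range(1, 11)} | {OUTGROUP_LABEL}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            assert node.edge.length > 0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label != OUTGROUP_LABEL:
            assert leaf.edge.length >= MIN_TERMINAL_BRANCH - 1e-12
    og = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == OUTGROUP_LABEL
    )
    assert og.edge.length == pytest.approx(OUTGROUP_BRANCH)
    assert og.parent_node is tree.seed_node


def test_species_tree_deterministic():
    a = simulate_species_tree(8, 1.0, 7)
    b = simulate_species_tree(8, 1.0, 7)
    assert write_newick(a) == write_newick(b)
    c = simulate_species_tree(8, 1.0, 8)
    assert write_newick(a) != write_newick(c)


def test_species_tree_min_taxa():
    with pytest.raises(ValueError):
        simulate_species_tree(2, 1.0, 0)


def test_evolve_proteins_shapes_and_divergence():
    tree = simulate_species_tree(6, 1.0, 3)
    panel = evolve_proteins(tree, n_loci=5, locus_length=100, seed=3)
    assert set(panel) == leaf_labels(tree)
    for by_locus in panel.values():
        assert len(by_locus) == 5
        for seq in by_locus.values():
            assert seq.shape == (100,)
            assert seq.dtype == np.uint8
            assert seq.max() < 20
    # closely related tips differ less than tips across the root
    labels = sorted(leaf_labels(tree) - {"OUTGROUP"})
    a, b = labels[0], labels[1]

    def frac_diff(x, y):
        return float(np.mean(panel[x]["L0000"] != panel[y]["L0000"]))

    assert frac_diff(a, a) == 0.0
    assert frac_diff(a, "OUTGROUP") > 0.0


def test_evolve_proteins_validation():
    tree = simulate_species_tree(4, 1.0, 0)
    with pytest.raises(ValueError):
        evolve_proteins(tree, 1, 10, 0)


def test_occupancy_outgroup_complete():
    tree = simulate_species_tree(6, 1.0, 2)
    panel = evolve_proteins(tree, 20, 50, 2)
    mask, reduced = apply_occupancy(panel, 0.5, 2)
    assert mask[OUTGROUP_LABEL].all()
    assert len(reduced[OUTGROUP_LABEL]) == 20
    for taxon, by_locus in reduced.items():
        assert len(by_locus) == int(mask[taxon].sum())


def test_residue_codon_round_trip():
    seq = np.arange(20, dtype=np.uint8)
    residues = to_residues(seq)
    assert residues == AMINO_ACIDS
    nt = back_translate(seq)
    assert len(nt) == 60


def test_make_query_mag_divergence_and_completeness():
    tree = simulate_species_tree(5, 1.0, 4)
    panel = evolve_proteins(tree, 30, 100, 4)
    full = make_query_mag(panel, QuerySpec("q1", "T01", 0.05), seed=4)
    assert len(full.proteome) == 30
    diffs = [
        float(np.mean(full.proteome[lo] != panel["T01"][lo]))
        for lo in full.proteome
    ]
    assert 0.0 < np.mean(diffs) < 0.15
    partial = make_query_mag(
        panel, QuerySpec("q2", "T01", 0.05, completeness=0.5), seed=4
    )
    assert 0 < len(partial.proteome) < 30
    assert full.scaffolds and all(len(s) >= 1 for _, s in full.scaffolds)


def test_make_query_mag_contamination_adds_copies():
    tree = simulate_species_tree(5, 1.0, 4)
    panel = evolve_proteins(tree, 30, 100, 4)
    mag = make_query_mag(
        panel, QuerySpec("q3", "T01", 0.01, contamination=0.5), seed=4
    )
    assert any(lo.endswith(".c") for lo in mag.proteome)


def test_make_query_mag_unknown_reference():
    tree = simulate_species_tree(4, 1.0, 0)
    panel = evolve_proteins(tree, 5, 50, 0)
    with pytest.raises(KeyError):
        make_query_mag(panel, QuerySpec("q", "T99", 0.01), seed=0)


def test_pileup_statistics_match_model():
    t = simulate_pileup("m", 50.0, 100_000, 0.3, 0.01, seed=1)
    assert (t["alt_count"] <= t["depth"]).all()
    assert t["pos"].min() >= 1
    mean_depth = t["depth"].sum() / 100_000
    # NB variance = mu + mu^2/k = 300; SE of the mean over 1e5 sites
    se = np.sqrt(300.0 / 100_000)
    assert abs(mean_depth - 50.0) < 4 * se


def test_pileup_deterministic_and_validated():
    a = simulate_pileup("m", 5.0, 1_000, 0.0, 0.0, seed=2)
    b = simulate_pileup("m", 5.0, 1_000, 0.0, 0.0, seed=2)
    assert a.equals(b)
    with pytest.raises(ValueError):
        simulate_pileup("m", 0.0, 10, 0.0, 0.0, seed=0)
    with pytest.raises(ValueError):
        simulate_pileup("m", 5.0, 10, 0.9, 0.0, seed=0)


def test_expected_alt_positions_zero_without_strain():
    mean, sd = expected_alt_positions(50.0, 1_000, 0.0, 0.0)
    assert mean == 0.0 and sd == 0.0


def test_generate_all_structure_and_files(tmp_path):
    config = SimConfig(
        seed=5,
        n_ref_taxa=5,
        n_loci=10,
        locus_length=60,
        query_specs=[QuerySpec("CF01_bin_1", "T02", 0.01)],
        community_specs=[CommunityMember("CF01", "CF01_bin_1", 10.0, 5_000)],
    )
    out = generate_all(config, outdir=tmp_path)
    assert set(out["queries"]) == {"CF01_bin_1"}
    truth = out["truth"]
    assert truth.true_assignments["CF01_bin_1"][0] == "conspecific"
    assert (tmp_path / "true_tree.nwk").exists()
    assert (tmp_path / "bins" / "CF01_bin_1.fasta").exists()
    assert (tmp_path / "proteomes" / "T01.fasta").exists()
    assert (tmp_path / "config_echo.yaml").exists()
    # config round-trips through the echo file
    back = SimConfig.from_yaml(tmp_path / "config_echo.yaml")
    assert back == config


def test_truth_categories_by_divergence():
    from magphylo.synthgen import _truth_category

    assert _truth_category(QuerySpec("q", "T01", 0.01))[0] == "conspecific"
    assert _truth_category(QuerySpec("q", "T01", 0.05))[0] == "provisional_species"
    assert _truth_category(QuerySpec("q", "T01", 0.15))[0] == "family_level"
    assert _truth_category(QuerySpec("q", "T01", 0.5))[0] == "rejected_long_branch"
    assert (
        _truth_category(QuerySpec("q", "T01", 0.01, chimera_with="T02"))[0]
        == "rejected_long_branch"
    )


def test_substreams_independent():
    # the same named substream yields identical draws regardless of what
    # other generators ran before it
    tree1 = simulate_species_tree(5, 1.0, 9)
    _ = evolve_proteins(tree1, 5, 50, 9)
    tree2 = simulate_species_tree(5, 1.0, 9)
    assert write_newick(tree1) == write_newick(tree2)
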