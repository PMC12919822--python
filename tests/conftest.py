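"""Shared fixtures: small taxonomies and hand-built trees."""

import dendropy
import pytest
from hypothesis import HealthCheck, settings

from magphylo.datasets import coffee_mag_evidence, coffee_taxonomy
from magphylo.taxonomy import Taxonomy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coffee_tax() -> Taxonomy:
    return coffee_taxonomy()


@pytest.fixture(scope="session")
def coffee_evidence():
    return coffee_mag_evidence()


@pytest.fixture()
def tiny_taxonomy() -> Taxonomy:
    """root -> F1(G1: A,B; G2: C) + F2(G3: D)."""
    tax = Taxonomy()
    tax.add_node("root", None, "order")
    tax.add_node("F1", "root", "family")
    tax.add_node("F2", "root", "family")
    tax.add_node("G1", "F1", "genus", 1_000_000)
    tax.add_node("G2", "F1", "genus", 2_000_000)
    tax.add_node("G3", "F2", "genus", 3_000_000)
    tax.add_node("A", "G1", "species")
    tax.add_node("B", "G1", "species")
    tax.add_node("C", "G2", "species")
    tax.add_node("D", "G3", "species")
    return tax


def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
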