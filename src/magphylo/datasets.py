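"""Bundled worked-example data: a coffee-fermentation yeast MAG survey.

Twenty-two yeast MAGs recovered from nine spontaneous coffee-fermentation
metagenomes (samples CF02-CF18), with the phylogenomic evidence each MAG
carries: nearest reference genome, patristic distance to it (substitutions
per site), the number of reference species co-clustered or attached as the
immediate sister group, intra-clade distance range among co-clustered
MAGs, and the stem bootstrap support of the containing clade. Distances
are as reported by the survey; per-sample mean depths are included where
reported (NaN where not).

These tables let the classifier and the community summaries run as a
worked example without any sequence data.
"""

from __future__ import annotations

import pandas as pd

from .classify import Assignment, ClassifyParams, classify_from_evidence
from .taxonomy import Taxonomy

SAMPLES = ("CF02", "CF08", "CF09", "CF12", "CF13", "CF14", "CF15", "CF16", "CF18")


def coffee_taxonomy() -> Taxonomy:
    """Taxonomy for the survey's reference species.

    *Candida* (sensu lato) is flagged unstable: the genus is polyphyletic,
    so queries anchored to it fall back to a family-level label. Genus
    median genome sizes (bp) are included for the genome-size filter.
    """
    tax = Taxonomy()
    tax.add_node("Saccharomycotina", None, "subphylum")
    for cls in ("Pichiomycetes", "Saccharomycetes"):
        tax.add_node(cls, "Saccharomycotina", "class")
    tax.add_node("Pichiales", "Pichiomycetes", "order")
    tax.add_node("Serinales", "Pichiomycetes", "order")
    tax.add_node("Saccharomycetales", "Saccharomycetes", "order")
    tax.add_node("Pichiaceae", "Pichiales", "family")
    tax.add_node("Debaryomycetaceae", "Serinales", "family")
    tax.add_node("Saccharomycodaceae", "Saccharomycetales", "family")
    tax.add_node("Saccharomycetaceae", "Saccharomycetales", "family")
    tax.add_node("Pichia", "Pichiaceae", "genus", 5.2e6)
    tax.add_node("Hanseniaspora", "Saccharomycodaceae", "genus", 9.0e6)
    tax.add_node("Torulaspora", "Saccharomycetaceae", "genus", 9.2e6)
    tax.add_node("Kurtzmaniella", "Debaryomycetaceae", "genus", 10.5e6)
    tax.add_node("Candida", "Debaryomycetaceae", "genus", 11.5e6, unstable=True)
    species = {
        "Pichia": ["Pichia kluyveri", "Pichia heedii", "Pichia kudriavzevii"],
        "Hanseniaspora": [
            "Hanseniaspora opuntiae",
            "Hanseniaspora pseudoguilliermondii",
            "Hanseniaspora guilliermondii",
            "Hanseniaspora lachancei",
            "Hanseniaspora meyeri",
            "Hanseniaspora clermontiae",
            "Hanseniaspora nectarophila",
            "Hanseniaspora uvarum",
        ],
        "Torulaspora": ["Torulaspora delbrueckii"],
        "Kurtzmaniella": [
            "Kurtzmaniella quercitrusa",
            "Kurtzmaniella natalensis",
            "Kurtzmaniella fragi",
            "Kurtzmaniella cleridarum",
        ],
        "Candida": ["Candida oleophila", "Candida corydali", "Candida sojae"],
    }
    for genus, names in species.items():
        for name in names:
            tax.add_node(name, genus, "species")
    return tax


def coffee_mag_evidence() -> pd.DataFrame:
    """Per-MAG evidence table for the 22 retained yeast MAGs.

    d_nearest values are the survey's reported branch lengths; mean_depth
    (x coverage) is reported where available.
    """

    cols = (
        "query_id",
        "nearest_ref",
        "d_nearest",
        "n_refs_equally_near",
        "intra_min",
        "intra_max",
        "clade_support",
        "mean_depth",
    )

    def rows(entries):
        return [dict(zip(cols, e)) for e in entries]

    pichia = rows(
        [
            (f"{s}_bin_1", "Pichia kluyveri", 0.0070, 1, 0.0008, 0.0098, 100, dep)
            for s, dep in [
                ("CF02", 55.7),
                ("CF08", 142.0),
                ("CF09", 5.91),
                ("CF12", 45.5),
                ("CF13", None),
                ("CF14", 42.5),
                ("CF15", 65.7),
                ("CF16", 54.6),
                ("CF18", 45.9),
            ]
        ]
    )
    opuntiae = rows(
        [
            ("CF09_bin_2", "Hanseniaspora opuntiae", 0.0011, 1, 0.0011, 0.016, 100, 10.0),
            ("CF15_bin_2", "Hanseniaspora opuntiae", 0.0080, 1, 0.0011, 0.016, 100, None),
            ("CF16_bin_2", "Hanseniaspora opuntiae", 0.0160, 1, 0.0011, 0.016, 100, 14.9),
        ]
    )
    novel_hans = rows(
        [
            ("CF02_bin_2", "Hanseniaspora uvarum", 0.032, 4, 0.0044, 0.0234, 100, 9.8),
            ("CF12_bin_2", "Hanseniaspora uvarum", 0.054, 4, 0.0044, 0.0234, 100, None),
            ("CF15_bin_3", "Hanseniaspora uvarum", 0.077, 4, 0.0044, 0.0234, 100, 41.7),
        ]
    )
    torulaspora = rows(
        [
            ("CF09_bin_3", "Torulaspora delbrueckii", 0.0040, 1, None, None, 100, 7.2),
            ("CF12_bin_3", "Torulaspora delbrueckii", 0.0060, 1, None, None, 100, 8.0),
        ]
    )
    kurtzmaniella = rows(
        [
            ("CF02_bin_3", "Kurtzmaniella quercitrusa", 0.0731, 1, 0.00066, 0.0038, 100, 8.7),
            ("CF09_bin_4", "Kurtzmaniella quercitrusa", 0.0731, 1, 0.00066, 0.0038, 100, 16.3),
            ("CF15_bin_4", "Kurtzmaniella quercitrusa", 0.0731, 1, 0.00066, 0.0038, 100, None),
        ]
    )
    debaryo = rows(
        [
            ("CF02scaffolds_bin_4", "Candida oleophila", 0.1082, 1, None, None, 100, 6.5),
            ("CF14scaffolds_bin_31", "Candida corydali", 0.0386, 1, None, None, 100, 20.3),
        ]
    )
    return pd.DataFrame(
        pichia + opuntiae + novel_hans + torulaspora + kurtzmaniella + debaryo,
        columns=cols,
    )


def coffee_assignments(params: ClassifyParams | None = None) -> list[Assignment]:
    """Classify the bundled evidence table with the default cascade."""
    return classify_from_evidence(
        coffee_mag_evidence(), coffee_taxonomy(), params or ClassifyParams()
    )
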