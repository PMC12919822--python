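"""Lowest-common-ancestor read/scaffold classification.

Implements the MEGAN-style LCA rule: discard weak hits (bit score below a
floor, e-value above a cap), keep hits within a top-percent band of the
best surviving bit score, and assign the query to the LCA of the kept
subject taxa. Defaults are min score 50 bits, top percent 10, max
expected 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .taxonomy import Taxonomy

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_taxon: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.bit_score < 0 or self.e_value < 0:
            raise ValueError("bit_score and e_value must be non-negative")


@dataclass(frozen=True)
class LCAParams:
    min_score: float = 50.0
    top_percent: float = 10.0
    max_expected: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.top_percent <= 100):
            raise ValueError("top_percent must be in (0, 100]")


def lca_assign(
    hits: list[HitRecord], params: LCAParams, taxonomy: Taxonomy
) -> str:
    """Assign one query's hit list to a taxonomy node, or ``unassigned``.

    Comparisons use >= / <= so exact floating-point ties at the band edge
    are kept.
    """
    for h in hits:
        if h.subject_taxon not in taxonomy:
            raise ValueError(f"hit names unknown taxon {h.subject_taxon!r}")
    survivors = [
        h
        for h in hits
        if h.bit_score >= params.min_score and h.e_value <= params.max_expected
    ]
    if not survivors:
        return UNASSIGNED
    best = max(h.bit_score for h in survivors)
    band = (1.0 - params.top_percent / 100.0) * best
    kept = [h.subject_taxon for h in survivors if h.bit_score >= band]
    return taxonomy.lca(kept)


def read_hits_tsv(path: str | Path) -> dict[str, list[HitRecord]]:
    """Load a BLAST-outfmt-6-compatible hit table, grouped by query.

    Required columns: query, subject_taxon, bit_score, e_value.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[HitRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.query), []).append(
            HitRecord(
                str(row.query),
                str(row.subject_taxon),
                float(row.bit_score),
                float(row.e_value),
            )
        )
    return out
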