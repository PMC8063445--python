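"""Disease-signature selection and set overlaps.

A gene belongs to the signature of a contrast when ``|logFC| >= logfc_min``
and ``adj_p <= adj_p_max`` (both boundaries inclusive; defaults 1.0 log2
units and 0.05). The extended altered set is the union of such selections
over several contrasts — e.g. disease vs healthy plus each treatment vs
healthy — capturing genes a treatment perturbs even though the disease does
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .diffexpr import ContrastResult

__all__ = [
    "GeneSignature",
    "select_signature",
    "extended_altered_set",
    "overlap_table",
]


@dataclass
class GeneSignature:
    """A named gene set selected from one or more contrasts at recorded thresholds."""

    name: str
    members: set[str]
    source_contrasts: list[str] = field(default_factory=list)
    thresholds: tuple[float, float] = (1.0, 0.05)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def select_signature(
    contrast: ContrastResult,
    logfc_min: float = 1.0,
    adj_p_max: float = 0.05,
    name: str | None = None,
) -> GeneSignature:
    """Genes with ``|logFC| >= logfc_min`` and ``adj_p <= adj_p_max``."""
    if logfc_min <= 0 or adj_p_max <= 0:
        raise ValueError("thresholds must be positive")
    tbl = contrast.table
    mask = (tbl["logFC"].abs() >= logfc_min) & (tbl["adj_p"] <= adj_p_max)
    return GeneSignature(
        name=name or f"signature_{contrast.contrast_id}",
        members=set(tbl.index[mask]),
        source_contrasts=[contrast.contrast_id],
        thresholds=(logfc_min, adj_p_max),
    )


def extended_altered_set(
    contrasts: list[ContrastResult],
    logfc_min: float = 1.0,
    adj_p_max: float = 0.05,
    name: str = "extended_altered_set",
) -> GeneSignature:
    """Union of per-contrast selections at shared thresholds.

    All contrasts must cover the same gene universe so that membership is
    decided for every gene in every contrast.
    """
    if not contrasts:
        raise ValueError("at least one contrast is required")
    universe = set(contrasts[0].gene_ids)
    for c in contrasts[1:]:
        if set(c.gene_ids) != universe:
            raise ValueError(
                f"contrast {c.contrast_id!r} has a different gene universe"
            )
    members: set[str] = set()
    for c in contrasts:
        members |= select_signature(c, logfc_min, adj_p_max).members
    return GeneSignature(
        name=name,
        members=members,
        source_contrasts=[c.contrast_id for c in contrasts],
        thresholds=(logfc_min, adj_p_max),
    )


def overlap_table(signatures: list[GeneSignature]) -> pd.DataFrame:
    """Exclusive-intersection counts over every combination of signatures.

    One row per non-empty combination: boolean membership flags (one column
    per signature name), the count of genes belonging to exactly that
    combination, and the genes themselves. Rows with zero count are omitted;
    the counts sum to the size of the union.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures for an overlap table")
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")
    union = set().union(*(s.members for s in signatures))
    rows = []
    for r in range(len(signatures), 0, -1):
        for combo in combinations(range(len(signatures)), r):
            in_sets = set(combo)
            genes = [
                g
                for g in sorted(union)
                if all(
                    (g in signatures[i].members) == (i in in_sets)
                    for i in range(len(signatures))
                )
            ]
            if not genes:
                continue
            row = {name: (i in in_sets) for i, name in enumerate(names)}
            row["count"] = len(genes)
            row["genes"] = ",".join(genes)
            rows.append(row)
    return pd.DataFrame(rows, columns=[*names, "count", "genes"])
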