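"""Per-functional-category treatment efficiency scores.

For a gene-set category C and a treatment T the score is

    score(C, T) = log10( mean_{g in C} |logFC_{T vs disease}(g)|
                        / mean_{g in C} |logFC_{T vs healthy}(g)| )

A high score means the treatment moved the category's genes far from the
disease state while leaving them close to the healthy state — effective
restoration without disruption of the healthy profile. Negative scores mean
the category sits closer to disease than to health under that treatment.
Both means are floored at a small epsilon before the ratio so the score is
finite when a treatment exactly matches one of the baselines; flags record
when the floor fired. Categories whose best score across treatments exceeds
a threshold (default 1, i.e. a tenfold ratio) pass the filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult
from .errors import ConfigError, EmptyAnnotationWarning
from .io import GeneSetCollection
from .restoration import ClusterAssignment, ProfileMatrix, ward_cluster
from .signature import GeneSignature

__all__ = [
    "CategoryEfficiencyTable",
    "map_categories",
    "efficiency_scores",
    "cluster_categories",
]

#: floor (log2 units) applied to mean displacements before the log10 ratio
DEFAULT_EPSILON = 0.01
#: minimum surviving members for a category after intersection with the universe
DEFAULT_MIN_SET_SIZE = 5
#: a category passes when its best score across treatments exceeds this
DEFAULT_SCORE_FILTER = 1.0


@dataclass
class CategoryEfficiencyTable:
    """Long-format efficiency table: one row per (category, treatment).

    Columns: ``category, treatment, n_genes_used, mean_abs_logfc_vs_disease,
    mean_abs_logfc_vs_wt, efficiency_score, floored_numerator,
    floored_denominator, passes_filter`` and, after ``cluster_categories``,
    ``category_cluster``.
    """

    table: pd.DataFrame
    epsilon: float
    score_filter: float

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.table["category"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.table["treatment"]))

    def score_matrix(self) -> pd.DataFrame:
        """Categories x treatments matrix of efficiency scores."""
        wide = self.table.pivot(
            index="category", columns="treatment", values="efficiency_score"
        )
        return wide.loc[self.categories, self.treatments]

    def passing_categories(self) -> list[str]:
        passing = self.table.loc[self.table["passes_filter"], "category"]
        return list(dict.fromkeys(passing))


def map_categories(
    sets: GeneSetCollection,
    universe: GeneSignature,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> GeneSetCollection:
    """Intersect every category with the gene universe; drop small leftovers."""
    if len(universe) == 0:
        raise ValueError("universe is empty")
    surviving: dict[str, tuple[str, list[str]]] = {}
    for set_id, (description, members) in sets.sets.items():
        kept = [g for g in members if g in universe]
        if len(kept) >= min_set_size:
            surviving[set_id] = (description, kept)
    if not surviving:
        warnings.warn(
            "no gene set retained >= "
            f"{min_set_size} members after intersection with the universe",
            EmptyAnnotationWarning,
            stacklevel=2,
        )
    return GeneSetCollection(surviving)


def efficiency_scores(
    categories: GeneSetCollection,
    contrasts_vs_wt: dict[str, ContrastResult],
    contrasts_vs_disease: dict[str, ContrastResult],
    epsilon: float = DEFAULT_EPSILON,
    score_filter: float = DEFAULT_SCORE_FILTER,
) -> CategoryEfficiencyTable:
    """Score every (category, treatment) pair.

    ``contrasts_vs_wt`` and ``contrasts_vs_disease`` map each treatment name
    to its contrast against the healthy baseline and against the disease
    group respectively; both must cover a shared gene universe.
    """
    if epsilon <= 0:
        raise ConfigError("epsilon must be > 0")
    treatments = list(contrasts_vs_wt)
    if set(treatments) != set(contrasts_vs_disease):
        raise ValueError("vs-WT and vs-disease contrasts must cover the same treatments")
    rows = []
    for set_id in categories.set_ids:
        members = categories.members(set_id)
        for t in treatments:
            vs_dis = contrasts_vs_disease[t].table
            vs_wt = contrasts_vs_wt[t].table
            missing = [g for g in members if g not in vs_dis.index or g not in vs_wt.index]
            if missing:
                warnings.warn(
                    f"category {set_id!r} has members outside the contrast "
                    f"universe; skipped ({missing[:3]} ...)",
                    stacklevel=2,
                )
                break
            num = float(vs_dis.loc[members, "logFC"].abs().mean())
            den = float(vs_wt.loc[members, "logFC"].abs().mean())
            floored_num = num < epsilon
            floored_den = den < epsilon
            score = math.log10(max(num, epsilon) / max(den, epsilon))
            rows.append(
                {
                    "category": set_id,
                    "treatment": t,
                    "n_genes_used": len(members),
                    "mean_abs_logfc_vs_disease": num,
                    "mean_abs_logfc_vs_wt": den,
                    "efficiency_score": score,
                    "floored_numerator": floored_num,
                    "floored_denominator": floored_den,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "category",
            "treatment",
            "n_genes_used",
            "mean_abs_logfc_vs_disease",
            "mean_abs_logfc_vs_wt",
            "efficiency_score",
            "floored_numerator",
            "floored_denominator",
        ],
    )
    if len(table):
        best = table.groupby("category")["efficiency_score"].transform("max")
        table["passes_filter"] = best > score_filter
    else:
        table["passes_filter"] = pd.Series(dtype=bool)
    return CategoryEfficiencyTable(
        table=table, epsilon=epsilon, score_filter=score_filter
    )


def cluster_categories(
    table: CategoryEfficiencyTable, k: int = 3
) -> tuple[ClusterAssignment, CategoryEfficiencyTable]:
    """Ward-cluster the filtered categories by their score vectors.

    Only categories passing the score filter are clustered (as in a display
    restricted to effective categories). Returns the assignment and a copy of
    the table with a ``category_cluster`` column (absent categories get NA).
    """
    passing = table.passing_categories()
    if len(passing) < k:
        raise ValueError(
            f"only {len(passing)} categories pass the filter; cannot cut {k} clusters"
        )
    scores = table.score_matrix().loc[passing]
    profile = ProfileMatrix(scores)
    assignment = ward_cluster(profile, k=k)
    labels = dict(zip(assignment.item_ids, assignment.labels))
    annotated = table.table.copy()
    annotated["category_cluster"] = annotated["category"].map(labels).astype("Int64")
    return assignment, CategoryEfficiencyTable(
        table=annotated, epsilon=table.epsilon, score_filter=table.score_filter
    )
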