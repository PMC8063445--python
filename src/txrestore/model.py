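"""Model/results interface for the full restoration analysis.

``TreatmentRestorationModel`` holds the data (expression matrix, study
design, optional gene sets) and the analysis parameters; ``fit()`` runs the
whole chain — differential expression against the healthy baseline and the
disease group, disease-signature selection, Ward clustering of logFC
profiles, per-cluster distance from healthy, and per-category treatment
efficiency scores — and returns a ``RestorationResults`` carrying every
intermediate table plus a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import diffexpr, efficiency, restoration, signature as sig
from .diffexpr import ContrastResult
from .efficiency import CategoryEfficiencyTable
from .io import ExpressionMatrix, GeneSetCollection, StudyDesign
from .restoration import ClusterAssignment, ProfileMatrix
from .signature import GeneSignature

__all__ = ["TreatmentRestorationModel", "RestorationResults"]


@dataclass
class TreatmentRestorationModel:
    """Restoration analysis of treatment transcriptomes toward a healthy baseline.

    Parameters
    ----------
    expression, design : the log2 expression matrix and sample-to-group map.
    gene_sets : optional functional categories (GMT) for efficiency scoring.
    moderation : ``"moderated"`` (empirical-Bayes t, default) or ``"ordinary"``.
    logfc_min, adj_p_max : signature thresholds, |logFC| >= 1 and BH-adjusted
        p <= 0.05 by default.
    k_genes, k_categories : cluster counts for gene profiles (default 6) and
        for category score vectors (default 3).
    epsilon, min_set_size, score_filter : efficiency-score floor, minimum
        category size after intersection, and the pass threshold (score > 1).
    standardize_profiles : z-score gene rows before clustering (default off:
        raw logFC values are clustered).
    """

    expression: ExpressionMatrix
    design: StudyDesign
    gene_sets: GeneSetCollection | None = None
    moderation: str = "moderated"
    logfc_min: float = 1.0
    adj_p_max: float = 0.05
    k_genes: int = 6
    k_categories: int = 3
    epsilon: float = efficiency.DEFAULT_EPSILON
    min_set_size: int = efficiency.DEFAULT_MIN_SET_SIZE
    score_filter: float = efficiency.DEFAULT_SCORE_FILTER
    standardize_profiles: bool = False

    @classmethod
    def from_files(
        cls,
        expression_path,
        design_path,
        baseline: str,
        disease: str,
        gmt_path=None,
        **params,
    ) -> "TreatmentRestorationModel":
        from . import io

        expr = io.read_expression(expression_path)
        design = io.read_design(design_path, baseline=baseline, disease=disease)
        sets = io.read_gmt(gmt_path) if gmt_path else None
        return cls(expression=expr, design=design, gene_sets=sets, **params)

    def fit(self) -> "RestorationResults":
        design = self.design
        baseline = design.baseline_group
        disease = design.disease_group
        conditions = [disease, *design.treatment_groups]

        contrasts_vs_wt: dict[str, ContrastResult] = {}
        for group in conditions:
            contrasts_vs_wt[group] = diffexpr.compute_contrast(
                self.expression, design, group, baseline, moderation=self.moderation
            )
        contrasts_vs_disease: dict[str, ContrastResult] = {}
        for group in design.treatment_groups:
            contrasts_vs_disease[group] = diffexpr.compute_contrast(
                self.expression, design, group, disease, moderation=self.moderation
            )

        disease_signature = sig.select_signature(
            contrasts_vs_wt[disease],
            self.logfc_min,
            self.adj_p_max,
            name="disease_signature",
        )
        extended = sig.extended_altered_set(
            list(contrasts_vs_wt.values()), self.logfc_min, self.adj_p_max
        )

        profile = clusters = distance = None
        if len(disease_signature) > 0:
            profile = restoration.build_profile(
                list(contrasts_vs_wt.values()), disease_signature
            )
            k = min(self.k_genes, len(disease_signature))
            clusters = restoration.ward_cluster(
                profile, k=k, standardize=self.standardize_profiles
            )
            distance = restoration.distance_report(profile, clusters)

        efficiency_table = None
        category_clusters = None
        if self.gene_sets is not None and len(extended) > 0:
            mapped = efficiency.map_categories(
                self.gene_sets, extended, min_set_size=self.min_set_size
            )
            if len(mapped) > 0:
                efficiency_table = efficiency.efficiency_scores(
                    mapped,
                    contrasts_vs_wt={
                        t: contrasts_vs_wt[t] for t in design.treatment_groups
                    },
                    contrasts_vs_disease=contrasts_vs_disease,
                    epsilon=self.epsilon,
                    score_filter=self.score_filter,
                )
                n_pass = len(efficiency_table.passing_categories())
                if n_pass >= max(self.k_categories, 1) and self.k_categories >= 1:
                    category_clusters, efficiency_table = efficiency.cluster_categories(
                        efficiency_table, k=self.k_categories
                    )

        return RestorationResults(
            model=self,
            contrasts_vs_wt=contrasts_vs_wt,
            contrasts_vs_disease=contrasts_vs_disease,
            disease_signature=disease_signature,
            extended_set=extended,
            profile=profile,
            gene_clusters=clusters,
            distance=distance,
            efficiency_table=efficiency_table,
            category_clusters=category_clusters,
        )


@dataclass
class RestorationResults:
    """All tables produced by one fit of the restoration analysis."""

    model: TreatmentRestorationModel
    contrasts_vs_wt: dict[str, ContrastResult]
    contrasts_vs_disease: dict[str, ContrastResult]
    disease_signature: GeneSignature
    extended_set: GeneSignature
    profile: ProfileMatrix | None
    gene_clusters: ClusterAssignment | None
    distance: pd.DataFrame | None
    efficiency_table: CategoryEfficiencyTable | None
    category_clusters: ClusterAssignment | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def overall_distance(self) -> pd.Series:
        """Mean |logFC vs healthy| over signature genes, per condition."""
        if self.distance is None:
            raise ValueError("no signature genes; distances unavailable")
        return self.distance.loc["all"]

    def summary(self) -> str:
        design = self.model.design
        lines = [
            "Treatment restoration analysis",
            "==============================",
            f"genes: {self.model.expression.n_genes}   "
            f"samples: {self.model.expression.n_samples}",
            f"baseline: {design.baseline_group}   disease: {design.disease_group}   "
            f"treatments: {', '.join(design.treatment_groups) or '(none)'}",
            f"signature thresholds: |logFC| >= {self.model.logfc_min}, "
            f"adj_p <= {self.model.adj_p_max}",
            f"disease signature: {len(self.disease_signature)} genes",
            f"extended altered set: {len(self.extended_set)} genes",
        ]
        if self.distance is not None:
            lines.append("")
            lines.append("mean |logFC| distance from healthy (rows: all + clusters)")
            lines.append(self.distance.round(3).to_string())
        if self.efficiency_table is not None:
            n_cat = len(self.efficiency_table.categories)
            n_pass = len(self.efficiency_table.passing_categories())
            lines.append("")
            lines.append(
                f"functional categories scored: {n_cat}; "
                f"passing score > {self.efficiency_table.score_filter}: {n_pass}"
            )
            wide = self.efficiency_table.score_matrix()
            passing = self.efficiency_table.passing_categories()
            if passing:
                lines.append("efficiency scores of passing categories")
                lines.append(wide.loc[passing].round(3).to_string())
        return "\n".join(lines)

    def plot_distance(self, ax=None):
        """Bar chart of mean distance from healthy per condition and cluster."""
        if self.distance is None:
            raise ValueError("no signature genes; nothing to plot")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        self.distance.T.plot.bar(ax=ax)
        ax.set_ylabel("mean |logFC| vs healthy")
        ax.set_xlabel("condition")
        ax.legend(title="gene group", fontsize=8)
        return ax
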