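"""Synthetic expression data with known ground truth.

The generator emulates a small microarray study: one healthy baseline group,
one disease group, and several treatment groups, each with a few replicates
of log2 intensities. A chosen fraction of genes is perturbed in disease by a
log2 shift of at least one unit; each treatment restores an all-or-none
random subset of those genes back to the baseline mean and may additionally
perturb a small fraction of non-disease genes (off-target effects). Replicate
noise is Gaussian on the log2 scale.

Every random draw comes from one seeded generator in a fixed order (gene
baselines, disease assignment, effects, then per-treatment draws in treatment
order, then noise), so a configuration plus a seed pins the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSetCollection, StudyDesign

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_expression",
    "simulate_gene_sets",
]

DEFAULT_TREATMENT_PREFIX = "T"


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults mirror a three-replicate microarray comparison of one disease
    group against healthy controls with three treatment arms of increasing
    restorative strength; effect sizes are |log2 shift| >= 1 as in the
    disease-signature definition downstream.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    n_treatments: int = 3
    frac_disease_genes: float = 0.05
    effect_size_low: float = 1.0
    effect_size_high: float = 3.0
    frac_up: float = 0.5
    restoration_fractions: list[float] = field(default_factory=lambda: [0.4, 0.6, 0.9])
    off_target_frac: float = 0.02
    off_target_effect: float = 1.5
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    heteroscedastic_df: float | None = None
    baseline_name: str = "WT"
    disease_name: str = "TG"
    treatment_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.n_treatments < 0:
            raise ConfigError("n_treatments must be >= 0")
        for name, value in [
            ("frac_disease_genes", self.frac_disease_genes),
            ("frac_up", self.frac_up),
            ("off_target_frac", self.off_target_frac),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.effect_size_low < 0 or self.effect_size_high < self.effect_size_low:
            raise ConfigError("effect size range must satisfy 0 <= low <= high")
        if len(self.restoration_fractions) != self.n_treatments:
            raise ConfigError(
                "restoration_fractions must have one entry per treatment "
                f"({self.n_treatments}), got {len(self.restoration_fractions)}"
            )
        for r in self.restoration_fractions:
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"restoration fraction {r} outside [0, 1]")
        if self.heteroscedastic_df is not None and self.heteroscedastic_df <= 2:
            raise ConfigError("heteroscedastic_df must be > 2 for a finite mean")
        if self.treatment_names is not None:
            if len(self.treatment_names) != self.n_treatments:
                raise ConfigError("treatment_names length must equal n_treatments")
        if self.baseline_name == self.disease_name:
            raise ConfigError("baseline and disease group names must differ")

    @property
    def resolved_treatment_names(self) -> list[str]:
        if self.treatment_names is not None:
            return list(self.treatment_names)
        return [f"{DEFAULT_TREATMENT_PREFIX}{i + 1}" for i in range(self.n_treatments)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"simulation config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``genes`` has one row per gene: ``is_disease_gene``, ``disease_effect``
    (log2 shift in disease vs baseline; 0 iff not a disease gene), and per
    treatment ``restored_<T>`` (the disease shift removed under T) and
    ``off_target_<T>`` (the treatment-specific log2 shift, 0 if untouched).
    """

    genes: pd.DataFrame
    treatment_names: list[str]

    def __post_init__(self) -> None:
        is_dis = self.genes["is_disease_gene"].to_numpy(dtype=bool)
        eff = self.genes["disease_effect"].to_numpy(dtype=float)
        if not ((eff != 0) == is_dis).all():
            raise ConfigError("disease_effect must be nonzero exactly for disease genes")
        for t in self.treatment_names:
            restored = self.genes[f"restored_{t}"].to_numpy(dtype=bool)
            if (restored & ~is_dis).any():
                raise ConfigError("only disease genes can be restored")

    @property
    def disease_genes(self) -> list[str]:
        mask = self.genes["is_disease_gene"].to_numpy(dtype=bool)
        return list(self.genes.index[mask])

    def to_frame(self) -> pd.DataFrame:
        out = self.genes.copy()
        out.index.name = "gene_id"
        return out.reset_index()


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, StudyDesign, SimulationTruth]:
    """Draw one dataset (expression, design, truth) from the generative model.

    Group means are ``b_g`` (baseline), ``b_g + delta_g`` (disease) and
    ``b_g + (1 - r_gt) * delta_g + o_gt`` (treatment t), where ``delta_g`` is
    the disease shift, ``r_gt`` is the all-or-none restoration indicator and
    ``o_gt`` the off-target shift. Each observation adds N(0, noise_sd^2).
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    treatments = config.resolved_treatment_names

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    n_disease = int(round(config.frac_disease_genes * n_genes))
    disease_idx = rng.choice(n_genes, size=n_disease, replace=False)
    is_disease = np.zeros(n_genes, dtype=bool)
    is_disease[disease_idx] = True

    magnitudes = rng.uniform(
        config.effect_size_low, config.effect_size_high, size=n_genes
    )
    up = rng.random(n_genes) < config.frac_up
    delta = np.where(is_disease, np.where(up, magnitudes, -magnitudes), 0.0)

    restored = np.zeros((n_genes, len(treatments)), dtype=bool)
    off_target = np.zeros((n_genes, len(treatments)))
    for j, frac in enumerate(config.restoration_fractions):
        restored[:, j] = is_disease & (rng.random(n_genes) < frac)
        hit = (~is_disease) & (rng.random(n_genes) < config.off_target_frac)
        signs = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
        off_target[:, j] = np.where(hit, signs * config.off_target_effect, 0.0)

    if config.heteroscedastic_df is not None:
        d0 = config.heteroscedastic_df
        gene_sd = config.noise_sd * np.sqrt(d0 / rng.chisquare(d0, size=n_genes))
    else:
        gene_sd = np.full(n_genes, config.noise_sd)

    group_means = {config.baseline_name: baselines,
                   config.disease_name: baselines + delta}
    for j, t in enumerate(treatments):
        group_means[t] = (
            baselines + np.where(restored[:, j], 0.0, delta) + off_target[:, j]
        )

    sample_ids: list[str] = []
    sample_to_group: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for group, mean in group_means.items():
        for r in range(config.n_per_group):
            sid = f"{group}_{r + 1}"
            sample_ids.append(sid)
            sample_to_group[sid] = group
            noise = rng.normal(0.0, 1.0, size=n_genes) * gene_sd
            columns.append(mean + noise)

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.column_stack(columns), index=gene_ids, columns=sample_ids
        )
    )
    design = StudyDesign(
        sample_to_group=sample_to_group,
        baseline_group=config.baseline_name,
        disease_group=config.disease_name,
        treatment_groups=treatments,
    )
    truth_df = pd.DataFrame(
        {"is_disease_gene": is_disease, "disease_effect": delta}, index=gene_ids
    )
    for j, t in enumerate(treatments):
        truth_df[f"restored_{t}"] = restored[:, j]
        truth_df[f"off_target_{t}"] = off_target[:, j]
    truth = SimulationTruth(genes=truth_df, treatment_names=treatments)
    return matrix, design, truth


def simulate_gene_sets(
    truth: SimulationTruth,
    n_sets: int,
    set_size_low: int = 10,
    set_size_high: int = 40,
    disease_enrichment: float = 1.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Draw random gene sets, optionally enriched for disease genes.

    Members are sampled without replacement with disease genes upweighted by
    ``disease_enrichment`` (1.0 means uniform sampling, so the expected
    disease-gene fraction per set equals the global fraction).
    """
    if n_sets < 0:
        raise ConfigError("n_sets must be >= 0")
    if set_size_low < 2 or set_size_high < set_size_low:
        raise ConfigError("set sizes must satisfy 2 <= low <= high")
    gene_ids = np.asarray(truth.genes.index)
    if set_size_high > len(gene_ids):
        raise ConfigError("set_size_high exceeds the number of genes")
    if disease_enrichment <= 0:
        raise ConfigError("disease_enrichment must be > 0")
    rng = np.random.default_rng(seed)
    weights = np.where(
        truth.genes["is_disease_gene"].to_numpy(dtype=bool), disease_enrichment, 1.0
    )
    prob = weights / weights.sum()
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_low, set_size_high + 1))
        members = rng.choice(gene_ids, size=size, replace=False, p=prob)
        sets[f"SET{i + 1:04d}"] = (f"synthetic gene set {i + 1}", list(members))
    return GeneSetCollection(sets)
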