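"""One-config orchestration of the full analysis with a run manifest.

``run_pipeline`` validates a :class:`PipelineConfig`, fits the
:class:`~txrestore.model.TreatmentRestorationModel`, writes every stage
output as TSV into the output directory, and returns a manifest with the
SHA-256 checksum of each file plus an echo of every parameter that
influenced it. Identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io, signature as sig
from .errors import ConfigError, TxRestoreError
from .model import TreatmentRestorationModel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("txrestore")


@dataclass
class PipelineConfig:
    """Paths, group roles and parameters for one pipeline run.

    Defaults follow the analysis conventions: 6 gene clusters, 3 category
    clusters, |logFC| >= 1 with adj_p <= 0.05 for signatures, and a category
    pass threshold of score > 1.
    """

    expression: str
    design: str
    out_dir: str
    baseline_group: str
    disease_group: str
    gmt: str | None = None
    logfc_min: float = 1.0
    adj_p_max: float = 0.05
    k_genes: int = 6
    k_categories: int = 3
    epsilon: float = 0.01
    min_set_size: int = 5
    score_filter: float = 1.0
    moderation: str = "moderated"
    standardize_profiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moderation not in ("moderated", "ordinary"):
            raise ConfigError(f"unknown moderation mode {self.moderation!r}")
        for name in ("logfc_min", "adj_p_max", "epsilon"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.k_genes < 1 or self.k_categories < 1:
            raise ConfigError("cluster counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"pipeline config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config fields: {sorted(unknown)}")
        missing = {"expression", "design", "out_dir", "baseline_group",
                   "disease_group"} - set(raw)
        if missing:
            raise ConfigError(f"pipeline config missing fields: {sorted(missing)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _signature_frame(signature, contrasts, logfc_min, adj_p_max) -> pd.DataFrame:
    """One gene per row with a membership flag per source contrast."""
    genes = signature.sorted_members()
    out = pd.DataFrame({"gene_id": genes})
    for c in contrasts:
        selected = sig.select_signature(c, logfc_min, adj_p_max).members
        out[c.contrast_id] = [g in selected for g in genes]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as manifest.json)."""
    # fail fast on inputs before any computation
    for label, path in [("expression", config.expression), ("design", config.design)]:
        if not Path(path).is_file():
            raise ConfigError(f"{label} file not found: {path}")
    if config.gmt is not None and not Path(config.gmt).is_file():
        raise ConfigError(f"gmt file not found: {config.gmt}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = out_dir / name
        io.write_table(frame, path)
        written.append(path)
        return path

    stage = "load inputs"
    try:
        expr = io.read_expression(config.expression)
        design = io.read_design(
            config.design, baseline=config.baseline_group, disease=config.disease_group
        )
        sets = io.read_gmt(config.gmt) if config.gmt else None
        logger.info(
            "loaded %d genes x %d samples; groups: %s",
            expr.n_genes, expr.n_samples, ", ".join(design.all_groups),
        )

        stage = "fit model"
        model = TreatmentRestorationModel(
            expression=expr,
            design=design,
            gene_sets=sets,
            moderation=config.moderation,
            logfc_min=config.logfc_min,
            adj_p_max=config.adj_p_max,
            k_genes=config.k_genes,
            k_categories=config.k_categories,
            epsilon=config.epsilon,
            min_set_size=config.min_set_size,
            score_filter=config.score_filter,
            standardize_profiles=config.standardize_profiles,
        )
        results = model.fit()

        stage = "write outputs"
        for group, contrast in results.contrasts_vs_wt.items():
            emit(f"de_{group}_vs_{design.baseline_group}.tsv", contrast.to_frame())
        for group, contrast in results.contrasts_vs_disease.items():
            emit(f"de_{group}_vs_{design.disease_group}.tsv", contrast.to_frame())

        vs_wt = list(results.contrasts_vs_wt.values())
        emit(
            "signature.tsv",
            _signature_frame(
                results.disease_signature,
                [results.contrasts_vs_wt[design.disease_group]],
                config.logfc_min,
                config.adj_p_max,
            ),
        )
        emit(
            "extended_set.tsv",
            _signature_frame(
                results.extended_set, vs_wt, config.logfc_min, config.adj_p_max
            ),
        )

        if results.profile is not None:
            prof = results.profile.data.copy()
            prof.index.name = "gene_id"
            emit("profile.tsv", prof.reset_index())
            emit("clusters.tsv", results.gene_clusters.to_frame())
            emit("distance.tsv", results.distance.reset_index())

        if results.efficiency_table is not None:
            emit("efficiency.tsv", results.efficiency_table.table)

        per_contrast = [
            sig.select_signature(
                c, config.logfc_min, config.adj_p_max, name=c.contrast_id
            )
            for c in vs_wt
        ]
        if len(per_contrast) >= 2:
            emit("upset.tsv", sig.overlap_table(per_contrast))

        manifest = {
            "parameters": asdict(config),
            "groups": {
                "baseline": design.baseline_group,
                "disease": design.disease_group,
                "treatments": design.treatment_groups,
            },
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "signature_size": len(results.disease_signature),
            "extended_set_size": len(results.extended_set),
            "outputs": {
                p.name: _sha256(p) for p in sorted(written, key=lambda q: q.name)
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        logger.info("wrote %d output files to %s", len(written) + 1, out_dir)
        return manifest
    except TxRestoreError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
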