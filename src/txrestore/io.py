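"""Readers and writers for the pipeline's external artifacts.

All tabular artifacts are tab-separated text with a header row:

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  cells are log2-normalized intensities (the loader never transforms values);
* sample sheet — two columns ``sample_id`` and ``group``;
* gene sets — standard GMT (``set_id<TAB>description<TAB>member...``);
* result tables — plain TSV written with 12 significant digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    DuplicateIdError,
    MissingValueError,
    ParseError,
)

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression values, genes x samples.

    Wraps a :class:`pandas.DataFrame` whose index holds gene ids and whose
    columns hold sample ids. Construction validates uniqueness and finiteness.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.dtype.kind not in "fiu":
            raise ParseError("expression values must be numeric")
        if np.isnan(values).any():
            bad = self.data.index[np.isnan(values).any(axis=1)].tolist()
            raise MissingValueError(f"missing values in genes: {bad[:5]}")
        if not np.isfinite(values).all():
            raise ParseError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DesignError(f"samples not in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, sample_ids].copy())


@dataclass
class StudyDesign:
    """Assignment of samples to groups with designated baseline and disease.

    ``treatment_groups`` keeps the file/declaration order of every group that
    is neither the healthy baseline nor the disease group.
    """

    sample_to_group: dict[str, str]
    baseline_group: str
    disease_group: str
    treatment_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_group == self.disease_group:
            raise DesignError("baseline and disease groups must differ")
        groups = self.group_names()
        for g in (self.baseline_group, self.disease_group, *self.treatment_groups):
            if g not in groups:
                raise DesignError(f"group {g!r} has no samples")
        for t in self.treatment_groups:
            if t in (self.baseline_group, self.disease_group):
                raise DesignError(f"treatment group {t!r} collides with a baseline group")
        for g in (self.baseline_group, self.disease_group, *self.treatment_groups):
            if len(self.samples_of(g)) < 2:
                raise DesignError(f"group {g!r} has fewer than 2 samples")

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_to_group.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    @property
    def all_groups(self) -> list[str]:
        return [self.baseline_group, self.disease_group, *self.treatment_groups]


@dataclass
class GeneSetCollection:
    """Named gene sets: ``set_id -> (description, ordered unique members)``."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ParseError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ParseError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Load a genes x samples log2 expression TSV.

    First column holds gene ids, header row holds sample ids. Row and column
    order are preserved. Duplicated ids, non-numeric cells and missing values
    are hard errors.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate gene ids in {path}: {dups[:5]}")
    na_tokens = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        missing = raw.isin(na_tokens)
        if missing.any():
            genes = df.index[missing].tolist()
            raise MissingValueError(
                f"missing value(s) in column {col!r}, genes {genes[:5]}"
            )
        try:
            numeric[col] = raw.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in column {col!r}: {exc}") from exc
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_design(path, baseline: str, disease: str) -> StudyDesign:
    """Load a two-column sample sheet and split groups into roles.

    Every group label that is neither ``baseline`` nor ``disease`` becomes a
    treatment group, in order of first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"sample sheet {path} must have two columns")
    sample_col, group_col = df.columns[:2]
    samples = df[sample_col].tolist()
    if len(set(samples)) != len(samples):
        raise DesignError(f"duplicate sample ids in {path}")
    mapping = dict(zip(samples, df[group_col].tolist()))
    groups_in_order: list[str] = []
    for g in mapping.values():
        if g not in groups_in_order:
            groups_in_order.append(g)
    if baseline not in groups_in_order:
        raise DesignError(f"baseline group {baseline!r} absent from {path}")
    if disease not in groups_in_order:
        raise DesignError(f"disease group {disease!r} absent from {path}")
    treatments = [g for g in groups_in_order if g not in (baseline, disease)]
    return StudyDesign(
        sample_to_group=mapping,
        baseline_group=baseline,
        disease_group=disease,
        treatment_groups=treatments,
    )


def write_design(design: StudyDesign, path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(design.sample_to_group),
         "group": list(design.sample_to_group.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_id<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are dropped (first occurrence kept);
    blank lines are ignored; a line with fewer than three fields is malformed.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members: list[str] = []
            for m in fields[2:]:
                if m and m not in members:
                    members.append(m)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = (description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, (description, members) in collection.sets.items():
            fh.write("\t".join([set_id, description, *members]) + "\n")


def write_table(records: pd.DataFrame, path) -> None:
    """Write a results table as TSV with header and 12 significant digits."""
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _float_fmt(x: float) -> str:  # kept for symmetry with write_table's contract
    return "%.12g" % x if math.isfinite(x) else repr(x)
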