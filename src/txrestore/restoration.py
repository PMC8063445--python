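"""Clustering of logFC profiles and distance from the healthy baseline.

Signature genes are described by their vector of logFC-vs-healthy values
across conditions (disease and each treatment). Ward agglomerative
clustering on these vectors groups genes with a shared response pattern;
the distance report then measures, per condition and per cluster, the mean
absolute logFC against the healthy controls — zero means transcriptionally
indistinguishable from healthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .diffexpr import ContrastResult
from .signature import GeneSignature

__all__ = [
    "ProfileMatrix",
    "ClusterAssignment",
    "build_profile",
    "ward_cluster",
    "distance_report",
]


@dataclass
class ProfileMatrix:
    """logFC-vs-baseline values for signature genes across conditions."""

    data: pd.DataFrame  # genes x conditions

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("profile values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    """Flat clustering with its merge history.

    ``labels`` maps each item to a cluster index in 1..k; clusters are
    numbered by decreasing size (ties broken by the smallest member index).
    ``linkage`` is the scipy-format merge record (heights use the convention
    in which each merge height is the square root of the accumulated Ward
    criterion, i.e. non-decreasing along the agglomeration).
    """

    item_ids: list[str]
    labels: np.ndarray
    k: int
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.item_ids):
            raise ValueError("one label per item required")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def members(self, cluster: int) -> list[str]:
        return [g for g, lab in zip(self.item_ids, self.labels) if lab == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "cluster": self.labels})


def build_profile(
    contrasts_vs_wt: list[ContrastResult], signature: GeneSignature
) -> ProfileMatrix:
    """Assemble the genes x conditions logFC matrix for signature genes.

    Columns follow the given contrast order; rows follow the signature's
    sorted member order. Every contrast must cover every signature gene.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    if not contrasts_vs_wt:
        raise ValueError("at least one contrast is required")
    genes = signature.sorted_members()
    cols = {}
    for c in contrasts_vs_wt:
        missing = [g for g in genes if g not in c.table.index]
        if missing:
            raise ValueError(
                f"contrast {c.contrast_id!r} lacks signature gene(s) {missing[:5]}"
            )
        cols[c.contrast_id] = c.table.loc[genes, "logFC"].to_numpy()
    return ProfileMatrix(pd.DataFrame(cols, index=genes))


def _canonical_labels(raw_labels: np.ndarray, k: int) -> np.ndarray:
    """Renumber clusters 1..k by decreasing size, ties by smallest member index."""
    order = sorted(
        range(1, k + 1),
        key=lambda c: (-(raw_labels == c).sum(), int(np.argmax(raw_labels == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[int(lab)] for lab in raw_labels], dtype=int)


def ward_cluster(
    profile: ProfileMatrix, k: int, standardize: bool = False
) -> ClusterAssignment:
    """Ward agglomerative clustering of profile rows, cut to exactly k clusters.

    Merges minimize the increase in within-cluster sum of squares on the
    Euclidean geometry of the logFC vectors. ``standardize`` optionally
    z-scores each row (gene) before clustering, grouping by response shape
    rather than magnitude; the default clusters raw logFC values.
    """
    X = profile.values
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if n == 1:
        linkage = np.empty((0, 4))
        labels = np.array([1])
    else:
        linkage = hierarchy.linkage(X, method="ward")
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        labels = _canonical_labels(labels, k)
    return ClusterAssignment(
        item_ids=profile.gene_ids, labels=labels, k=k, linkage=linkage
    )


def distance_report(
    profile: ProfileMatrix, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Mean absolute logFC against the healthy baseline, per condition and cluster.

    Rows are ``all`` (every profile gene) followed by each cluster id;
    columns are the profile's conditions. The ``all`` row equals the
    size-weighted mean of the cluster rows.
    """
    if list(clusters.item_ids) != list(profile.gene_ids):
        raise ValueError("cluster assignment does not cover the profile genes")
    absvals = np.abs(profile.values)
    rows = {"all": absvals.mean(axis=0)}
    for c in range(1, clusters.k + 1):
        mask = clusters.labels == c
        rows[str(c)] = absvals[mask].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=profile.condition_ids)
    out.index.name = "gene_group"
    return out
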