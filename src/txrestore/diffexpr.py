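"""Per-gene differential expression between two sample groups.

For each gene the log2 fold change is the difference of group means of the
log2 expression values (first group minus second). Two test statistics are
offered:

* ``ordinary`` — the pooled-variance two-sample t with n_a + n_b - 2 degrees
  of freedom;
* ``moderated`` — an empirical-Bayes moderated t in which the per-gene pooled
  variance ``s_g^2`` is shrunk toward a prior variance ``s0^2`` fitted across
  genes: the posterior variance is ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and
  the statistic gains ``d0`` prior degrees of freedom. The prior parameters
  ``(d0, s0^2)`` are estimated by matching the first two moments of
  ``log s_g^2`` to a scaled-F sampling model, inverting the trigamma function
  with Newton's method. This is the standard stabilization for designs with
  only a handful of replicates per group.

P-values are two-sided from the t distribution; multiple testing is corrected
with the Benjamini-Hochberg step-up rule (reported as ``adj_p``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, ZeroVarianceWarning
from .io import ExpressionMatrix, StudyDesign

__all__ = ["ContrastResult", "compute_contrast", "adjust_bh"]

#: degrees of freedom treated as effectively infinite when computing p-values
_DF_CAP = 1e9


@dataclass
class ContrastResult:
    """Differential-expression table for one group-vs-group contrast.

    ``table`` is indexed by gene id with columns ``logFC`` (log2 units,
    group_a minus group_b), ``t``, ``df``, ``p`` and ``adj_p``.
    """

    contrast_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"logFC", "t", "df", "p", "adj_p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"contrast table missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def logfc(self) -> pd.Series:
        return self.table["logFC"]

    @property
    def adj_p(self) -> pd.Series:
        return self.table["adj_p"]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.index.name = "gene_id"
        return out.reset_index()

    @classmethod
    def from_frame(cls, contrast_id: str, frame: pd.DataFrame) -> "ContrastResult":
        table = frame.set_index("gene_id")
        return cls(contrast_id=contrast_id, table=table)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior degrees of freedom d0 and prior variance s0^2.

    Matches the mean and variance of ``log s_g^2`` (over genes with positive
    sample variance) to the scaled-F model implied by chi-square sampling of
    variances around a common prior. Returns ``(inf, exp(mean))`` when the
    observed spread of log variances is no larger than chi-square sampling
    alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        return np.inf, 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if positive.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _two_sided_p(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    df = np.minimum(df, _DF_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # keep p in (0, 1] so downstream filters and BH stay well defined
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def compute_contrast(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    group_a: str,
    group_b: str,
    moderation: str = "moderated",
) -> ContrastResult:
    """Differential expression of ``group_a`` versus ``group_b``.

    logFC is mean(group_a) - mean(group_b) per gene; the baseline/control
    group therefore goes second. ``moderation`` selects the ordinary pooled t
    or the empirical-Bayes moderated t.
    """
    if moderation not in ("moderated", "ordinary"):
        raise ValueError(f"unknown moderation mode: {moderation!r}")
    groups = design.group_names()
    for g in (group_a, group_b):
        if g not in groups:
            raise DesignError(f"unknown group label: {g!r}")
    samples_a = design.samples_of(group_a)
    samples_b = design.samples_of(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DesignError("both groups need >= 2 samples")
    a = matrix.subset_samples(samples_a).values
    b = matrix.subset_samples(samples_b).values
    n_a, n_b = a.shape[1], b.shape[1]

    logfc = a.mean(axis=1) - b.mean(axis=1)
    # pooled within-group variance with d = n_a + n_b - 2 df
    ss_a = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d_resid = float(n_a + n_b - 2)
    s2 = (ss_a + ss_b) / d_resid
    scale = np.sqrt(1.0 / n_a + 1.0 / n_b)

    d0, s0_sq = fit_variance_prior(s2, d_resid)
    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + d_resid * s2) / (d0 + d_resid)
        df_mod = d0 + d_resid
    else:
        s2_post = np.full_like(s2, s0_sq)
        df_mod = _DF_CAP

    zero = s2 == 0
    if moderation == "ordinary":
        t = np.zeros_like(logfc)
        nonzero = ~zero
        t[nonzero] = logfc[nonzero] / (np.sqrt(s2[nonzero]) * scale)
        df_col = np.full_like(logfc, d_resid)
        p = np.ones_like(logfc)
        p[nonzero] = _two_sided_p(t[nonzero], d_resid)
        # zero pooled variance: identical replicates. logFC == 0 is a clean
        # no-change call (t=0, p=1); logFC != 0 falls back to the moderated
        # statistic, which borrows a positive variance from the prior.
        problematic = zero & (logfc != 0)
        if problematic.any():
            warnings.warn(
                f"{int(problematic.sum())} gene(s) with zero pooled variance and "
                "nonzero logFC; moderated fallback used for these",
                ZeroVarianceWarning,
                stacklevel=2,
            )
            with np.errstate(divide="ignore"):
                t_fb = logfc[problematic] / (np.sqrt(s2_post[problematic]) * scale)
            t[problematic] = t_fb
            df_col[problematic] = df_mod
            p[problematic] = _two_sided_p(t_fb, df_mod)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (np.sqrt(s2_post) * scale)
        # posterior variance can only be zero if every gene is constant
        degenerate = ~np.isfinite(t)
        t[degenerate & (logfc == 0)] = 0.0
        t[degenerate & (logfc > 0)] = np.inf
        t[degenerate & (logfc < 0)] = -np.inf
        df_col = np.full_like(logfc, df_mod)
        p = _two_sided_p(t, df_mod)
        p[degenerate & (logfc == 0)] = 1.0
        t = np.where(np.isinf(t), np.sign(t) * 1e12, t)

    adj_p = adjust_bh(p)
    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "df": df_col, "p": p, "adj_p": adj_p},
        index=matrix.gene_ids,
    )
    return ContrastResult(contrast_id=f"{group_a}_vs_{group_b}", table=table)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
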