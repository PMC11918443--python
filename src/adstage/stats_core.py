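"""Statistical primitives for the substage analysis.

Conventions used throughout:

* Expression matrices are genes x samples (rows are genes).
* The clustering transform is X = log2(TPM + 1) - C with per-gene C chosen so
  that each gene's mean over the included individuals is zero.
* Welch's t-test (unequal variances, Welch-Satterthwaite df) is the two-group
  test; one-way ANOVA the omnibus test; Benjamini-Hochberg controls the FDR
  (significance threshold 0.1 unless stated otherwise).
* Size factors follow the median-of-ratios construction: the reference is the
  per-gene geometric mean over samples (genes with any zero count excluded)
  and a sample's factor is a quantile (median, or first/third quartile) of its
  per-gene ratios to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "center_log_expression",
    "welch_t",
    "welch_t_table",
    "anova_oneway",
    "anova_oneway_table",
    "bh_fdr",
    "SizeFactorSummary",
    "size_factors",
    "low_expression_filter",
    "pearson",
    "pearson_rows",
]

STAGES = ("NCI", "MCI", "AD")
DEFAULT_FDR = 0.1
DEFAULT_SPIKE_PREFIXES = ("ERCC-",)


def center_log_expression(tpm):
    """X = log2(TPM + 1) - C with per-gene mean over individuals equal to 0."""
    if isinstance(tpm, pd.DataFrame):
        x = np.log2(tpm.to_numpy(dtype=float) + 1.0)
        x -= x.mean(axis=1, keepdims=True)
        return pd.DataFrame(x, index=tpm.index, columns=tpm.columns)
    x = np.log2(np.asarray(tpm, dtype=float) + 1.0)
    return x - x.mean(axis=1, keepdims=True)


def welch_t(a, b):
    """Welch's two-tailed t-test for two samples.

    Zero variance in both groups is handled by convention: equal means give
    (t=0, p=1); unequal means give the limit (inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least two values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t requires finite values")
    t, p = welch_t_table(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


def welch_t_table(a, b):
    """Vectorised Welch t over rows of two genes x samples matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = va / na + vb / nb
    both_const = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(denom)
        df = denom**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * _sps.t.sf(np.abs(t), df)
    if both_const.any():
        eq = both_const & (ma == mb)
        ne = both_const & (ma != mb)
        t[eq], p[eq] = 0.0, 1.0
        if ne.any():
            warnings.warn(
                "zero variance in both groups with unequal means; p = 0 limit",
                stacklevel=2,
            )
            t[ne] = np.sign(mb[ne] - ma[ne]) * np.inf
            p[ne] = 0.0
    return t, p


def anova_oneway(groups):
    """One-way ANOVA F and two-sided p for a list of sample vectors."""
    mats = [np.asarray(g, dtype=float)[None, :] for g in groups]
    for g in mats:
        if g.shape[1] < 2:
            raise ValueError("anova_oneway requires at least two values per group")
        if not np.isfinite(g).all():
            raise ValueError("anova_oneway requires finite values")
    f, p = anova_oneway_table(mats)
    return float(f[0]), float(p[0])


def anova_oneway_table(group_mats):
    """Vectorised one-way ANOVA over rows of genes x samples matrices.

    Conventions: zero between-group variance gives (F=0, p=1); zero
    within-group variance with distinct means gives (inf, 0) with a warning.
    """
    mats = [np.asarray(g, dtype=float) for g in group_mats]
    ns = np.array([g.shape[1] for g in mats])
    n = int(ns.sum())
    k = len(mats)
    if k < 2:
        raise ValueError("anova requires at least two groups")
    means = np.stack([g.mean(axis=1) for g in mats])  # k x genes
    grand = (means * ns[:, None]).sum(axis=0) / n
    ss_between = ((means - grand) ** 2 * ns[:, None]).sum(axis=0)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(mats, means))
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = _sps.f.sf(f, df_b, df_w)
    flat = ss_between == 0
    f = np.where(flat, 0.0, f)
    p = np.where(flat, 1.0, p)
    degen = (ss_within == 0) & ~flat
    if degen.any():
        warnings.warn("zero within-group variance with distinct means; p = 0 limit",
                      stacklevel=2)
        f = np.where(degen, np.inf, f)
        p = np.where(degen, 0.0, p)
    return f, p


def bh_fdr(p, alpha: float = DEFAULT_FDR):
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class SizeFactorSummary:
    """Per-sample size factors at one ratio quantile, with their spread."""

    factors: pd.Series
    quantile: float
    dispersion_ratio: float  # sd(factors) / mean(factors)


def size_factors(counts, quantile: float = 0.5) -> SizeFactorSummary:
    """Quantile-of-ratios size factors (median-of-ratios at q=0.5)."""
    if isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=float)
        samples = counts.columns
    else:
        mat = np.asarray(counts, dtype=float)
        samples = pd.RangeIndex(mat.shape[1])
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    sub = mat[positive]
    ref = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / ref[:, None]
    factors = np.quantile(ratios, quantile, axis=0)
    return SizeFactorSummary(
        factors=pd.Series(factors, index=samples, name=f"size_factor_q{quantile}"),
        quantile=quantile,
        dispersion_ratio=float(factors.std(ddof=1) / factors.mean())
        if len(factors) > 1 else 0.0,
    )


def low_expression_filter(
    tpm: pd.DataFrame,
    stage: pd.Series,
    threshold: float = 0.1,
    spike_prefixes=DEFAULT_SPIKE_PREFIXES,
    mode: str = "all_groups",
) -> pd.Index:
    """Gene ids kept after the low-expression and spike-in filters.

    ``mode='all_groups'`` (default) drops a gene only when its mean TPM is
    below ``threshold`` in every stage group; ``mode='overall'`` uses the
    overall mean instead.
    """
    missing = set(tpm.columns) - set(stage.index)
    if missing:
        raise ValueError(f"samples without a stage label: {sorted(missing)[:5]}")
    if mode not in ("all_groups", "overall"):
        raise ValueError("mode must be 'all_groups' or 'overall'")
    if mode == "overall":
        low = tpm.mean(axis=1) < threshold
    else:
        groups = [tpm.loc[:, stage[stage == s].index.intersection(tpm.columns)]
                  for s in STAGES]
        below = [g.mean(axis=1) < threshold for g in groups if g.shape[1] > 0]
        low = np.logical_and.reduce(below) if below else pd.Series(False, tpm.index)
    spike = tpm.index.str.startswith(tuple(spike_prefixes)) if spike_prefixes else False
    keep = ~(np.asarray(low) | np.asarray(spike))
    return tpm.index[keep]


def pearson(x, y) -> float:
    """Pearson correlation; 0 by convention when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson requires equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson of two equal-shape matrices; constant rows give 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den == 0, 0.0, r)
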