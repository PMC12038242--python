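"""Negative-binomial differential expression and differential CLR.

A deliberately small re-implementation of the DESeq2-style workflow for
two-group contrasts: median-of-ratios size factors, method-of-moments
dispersion (no shrinkage, no independent filtering), a Wald test on the
log2 fold change of group means with NB variance mu + alpha*mu^2, and
Benjamini-Hochberg step-up adjustment.  Differential CLR — for which no
parametric model is appropriate, CLR being a ratio of small counts — is
tested by label permutation on log2(CLR + eps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_FLOOR = 1e-8


@dataclass
class DeThresholds:
    lfc_cut: float = 1.0
    padj_cut: float = 0.05
    clr_lfc_cut: float = 0.1
    clr_padj_cut: float = 0.2

    def __post_init__(self) -> None:
        if min(self.lfc_cut, self.padj_cut, self.clr_lfc_cut, self.clr_padj_cut) <= 0:
            raise ValueError("thresholds must be positive")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with all-positive counts the geometric mean across
    samples is the reference; a sample's factor is the median of its
    count/reference ratios.  Falls back to relative total counts when no
    feature is positive everywhere.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        import warnings

        warnings.warn(
            "no feature has positive counts in every sample; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=matrix.columns, name="size_factor")
    ref = counts[positive]
    log_geo = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def estimate_dispersion(
    matrix: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion on normalized counts.

    alpha = max((var - mean) / mean^2, 1e-8).  When a group vector is
    given the variance is pooled within groups so that a real expression
    difference does not masquerade as overdispersion.
    """
    norm = matrix.to_numpy(dtype=float) / factors.reindex(matrix.columns).to_numpy()
    mean = norm.mean(axis=1)
    if groups is None:
        var = norm.var(axis=1, ddof=1)
    else:
        g = pd.Series(groups).reindex(matrix.columns)
        ss = np.zeros(norm.shape[0])
        dof = 0
        for label in g.unique():
            cols = np.asarray(g == label)
            sub = norm[:, cols]
            if cols.sum() < 2:
                continue
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += cols.sum() - 1
        var = ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_FLOOR)
    return pd.Series(np.maximum(alpha, ALPHA_FLOOR), index=matrix.index, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{k >= i} p_(k) * m / k, capped at 1; NaNs are carried
    through and excluded from m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def nb_wald_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test.

    ``contrast = (column, reference_level, test_level)``; log2fc is
    test over reference.  Group means are fitted on size-factor
    normalized counts; the fold change uses a 0.5 pseudocount only when a
    group mean is exactly zero; the standard error comes from the NB
    variance mu + alpha*mu^2 by the delta method.  Features with zero
    counts everywhere get NA results.

    Returns a DESeq2-style frame: baseMean, log2FoldChange, lfcSE, stat,
    pvalue, padj.
    """
    col, ref_level, test_level = contrast
    labels = design.loc[list(matrix.columns), col]
    cols_a = labels[labels == ref_level].index
    cols_b = labels[labels == test_level].index
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"contrast levels {ref_level!r}/{test_level!r} not both present")
    if factors is None:
        factors = size_factors(matrix)
    if dispersion is None:
        dispersion = estimate_dispersion(matrix, factors, groups=labels)

    sf = factors.reindex(matrix.columns)
    norm = matrix / sf
    na, nb = len(cols_a), len(cols_b)
    mu_a = norm[cols_a].mean(axis=1).to_numpy()
    mu_b = norm[cols_b].mean(axis=1).to_numpy()
    alpha = dispersion.reindex(matrix.index).to_numpy()
    base_mean = norm.mean(axis=1).to_numpy()

    pseudo_a = np.where(mu_a == 0, 0.5, mu_a)
    pseudo_b = np.where(mu_b == 0, 0.5, mu_b)
    log2fc = np.log2(pseudo_b / pseudo_a)

    inv_sf_a = (1.0 / sf[cols_a].to_numpy()).sum()
    inv_sf_b = (1.0 / sf[cols_b].to_numpy()).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        # Var(mean of K_j/s_j) = (mu * sum 1/s_j + alpha mu^2 n) / n^2
        var_a = (pseudo_a * inv_sf_a + alpha * pseudo_a**2 * na) / na**2
        var_b = (pseudo_b * inv_sf_b + alpha * pseudo_b**2 * nb) / nb**2
        # delta method on log2 of each group mean
        se = np.sqrt(var_a / pseudo_a**2 + var_b / pseudo_b**2) / math.log(2.0)
        stat = log2fc / se
    # the dispersion is a per-feature plugin estimate, so the Wald
    # statistic has Student-like tails; a t reference with n-2 df keeps
    # the test calibrated at small n (normal tails are anti-conservative)
    df = max(na + nb - 2, 1)
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df)

    all_zero = matrix.sum(axis=1).to_numpy() == 0
    for arr in (log2fc, se, stat):
        arr[all_zero] = np.nan
    pvalue = np.where(all_zero, np.nan, pvalue)

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "dispersion": alpha,
        },
        index=matrix.index,
    )


def differential_clr(
    clr: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    n_perm: int = 1000,
    seed: int = 0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Permutation test on log2(CLR + eps) group-mean differences.

    The statistic doubles as the reported log2FoldChange.  Labels are
    permuted jointly across features; when the number of distinct
    arrangements is <= 10,000 they are enumerated exactly, and a
    degenerate space (< 20 arrangements) yields NA p-values.
    """
    col, ref_level, test_level = contrast
    labels = design.loc[list(clr.columns), col]
    cols = labels[labels.isin([ref_level, test_level])].index
    y = np.log2(clr[cols].to_numpy(dtype=float) + eps)
    is_b = (labels[cols] == test_level).to_numpy()
    na, nb = int((~is_b).sum()), int(is_b.sum())
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group for the CLR test")
    n = na + nb

    def stat_for(mask: np.ndarray) -> np.ndarray:
        return y[:, mask].mean(axis=1) - y[:, ~mask].mean(axis=1)

    observed = stat_for(is_b)
    n_arrangements = math.comb(n, nb)
    if n_arrangements < 20:
        pvals = np.full(y.shape[0], np.nan)
    elif n_arrangements <= 10_000:
        null = np.array(
            [stat_for(np.isin(np.arange(n), idx)) for idx in combinations(range(n), nb)]
        )
        pvals = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.ones(y.shape[0])  # identity permutation counts once
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=nb, replace=False)] = True
            exceed += np.abs(stat_for(mask)) >= np.abs(observed) - 1e-12
        pvals = exceed / (n_perm + 1)
    return pd.DataFrame(
        {
            "log2FoldChange": observed,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        },
        index=clr.index,
    )


def classify_significant(
    results: pd.DataFrame,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
) -> pd.Series:
    """Partition features into 'up' / 'down' / 'unchanged'.

    NA statistics are 'unchanged'.  Defaults are the abundance
    thresholds |log2FC| > 1, adjusted P < 0.05; pass the CLR cuts
    (0.1, 0.2) for differential-CLR results.
    """
    lfc = results["log2FoldChange"]
    padj = results["padj"]
    sig = (padj < padj_cut) & (lfc.abs() > lfc_cut) & lfc.notna() & padj.notna()
    out = pd.Series("unchanged", index=results.index)
    out[sig & (lfc > 0)] = "up"
    out[sig & (lfc < 0)] = "down"
    return out
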