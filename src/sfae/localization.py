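"""Per-gene localization quantities derived from the global cytosolic ratio.

With a global CR estimate theta in hand, per-fraction TPMs can be put on
an absolute scale: theta*TPM_cyto and (1-theta)*TPM_nuc are proportional
to molecule numbers in the cytosol and nucleus. This module computes the
resulting per-gene quantities (adjusted log2 Cyto/Nuc ratios, per-gene
cytosolic fractions), clusters genes across cell lines, summarizes
localization per RNA class and quantifies cross-cell-line variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from sfae._stats import RankSumResult, rank_sum_test

logger = logging.getLogger(__name__)

DEFAULT_MIN_EXPRESSION = 0.1


def per_gene_cr(theta: float, c, n):
    """Per-gene cytosolic fraction theta*c / (theta*c + (1-theta)*n).

    The abundance-weighted mean of this quantity over a TPM-normalized
    gene set recovers the global theta exactly. Entries with c = n = 0 are
    undefined and returned as NaN.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    num = theta * c
    den = num + (1.0 - theta) * n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def adjusted_log2_ratios(
    theta: float, c, n, min_expression: float = DEFAULT_MIN_EXPRESSION,
):
    """Absolute (CR-adjusted) log2 Cyto/Nuc ratios with an expression mask.

    Returns ``(ratios, mask)``: log2(theta*c) - log2((1-theta)*n) where both
    c and n meet ``min_expression`` (default 0.1 TPM); other entries are NaN
    with mask False.
    """
    if theta in (0.0, 1.0):
        raise ValueError("theta of exactly 0 or 1 makes all ratios infinite")
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    mask = (c >= min_expression) & (n >= min_expression)
    out = np.full(c.shape, np.nan)
    out[mask] = np.log2(theta * c[mask]) - np.log2((1.0 - theta) * n[mask])
    return out, mask


@dataclass
class ClusterResult:
    labels: pd.Series  # gene -> cluster index (ordered by mean adjusted ratio)
    composition: pd.DataFrame  # cluster x biotype percentages (rows sum to 100)
    chi2: float
    chi2_p: float


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row; rows with zero variance become all zeros."""
    arr = matrix.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def cluster_localization(
    matrix: pd.DataFrame,
    biotypes: pd.Series | dict,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """K-means clustering of genes on per-gene z-scored adjusted ratios.

    ``matrix`` is the adjusted log2 Cyto/Nuc ratio matrix (genes x cell
    lines); genes with any missing cell must be dropped by the caller.
    Cluster labels are re-ordered by ascending mean adjusted ratio so that
    label 0 is the most nuclear cluster, making labels stable across runs.
    A chi-square test of biotype x cluster association is attached.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix must be complete; drop genes with masked cells")
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} genes, got {len(matrix)}")
    z = zscore_rows(matrix)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z.to_numpy())
    # stable ordering: sort clusters by mean of the unscaled adjusted ratio
    means = [matrix.to_numpy()[raw == i].mean() if (raw == i).any() else np.inf
             for i in range(k)]
    order = np.argsort(means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = pd.Series(relabel[raw], index=matrix.index, name="cluster")

    bt = pd.Series(biotypes).reindex(matrix.index).fillna("unknown")
    contingency = pd.crosstab(labels, bt)
    composition = contingency.div(contingency.sum(axis=1), axis=0) * 100.0
    if contingency.shape[1] > 1:
        chi2, p = stats.chi2_contingency(contingency.to_numpy())[:2]
    else:
        chi2, p = 0.0, 1.0
    return ClusterResult(labels=labels, composition=composition,
                         chi2=float(chi2), chi2_p=float(p))


def class_median_ratios(
    ratios: pd.DataFrame, gene_classes: pd.Series | dict,
) -> pd.DataFrame:
    """Per cell line and RNA class: median adjusted log2 ratio and the
    fraction of genes with ratio > 0 (cytosol-preferring).

    ``ratios`` is genes x cell lines with NaN for masked cells. Returns a
    tidy frame with columns cell_line, gene_class, median_log2, frac_cyto,
    n_genes; an empty class in a cell line yields NaN and is logged.
    """
    classes = pd.Series(gene_classes).reindex(ratios.index)
    rows = []
    for cl in ratios.columns:
        col = ratios[cl]
        for cls, grp in col.groupby(classes):
            vals = grp.dropna()
            if vals.empty:
                logger.info("no %s genes with ratio in cell line %s", cls, cl)
                rows.append((cl, cls, np.nan, np.nan, 0))
            else:
                rows.append((cl, cls, float(vals.median()),
                             float((vals > 0).mean()), len(vals)))
    return pd.DataFrame(
        rows, columns=["cell_line", "gene_class", "median_log2", "frac_cyto", "n_genes"]
    )


def variation_stats(
    per_gene_cr_matrix: pd.DataFrame, min_cell_lines: int = 3,
) -> pd.DataFrame:
    """Cross-cell-line variation of the per-gene CR.

    For each gene with at least ``min_cell_lines`` unmasked (non-NaN)
    values: ``cr_max_diff`` = max - min and ``cr_variance`` = sample
    variance (ddof=1). Genes below the threshold are dropped (count
    logged).
    """
    counts = per_gene_cr_matrix.notna().sum(axis=1)
    keep = counts >= min_cell_lines
    dropped = int((~keep).sum())
    if dropped:
        logger.info("variation_stats: dropped %d genes with < %d cell lines",
                    dropped, min_cell_lines)
    sub = per_gene_cr_matrix.loc[keep]
    max_diff = sub.max(axis=1) - sub.min(axis=1)
    variance = sub.var(axis=1, ddof=1)
    variance[max_diff == 0] = 0.0  # keep the range/variance zero-sets identical
    return pd.DataFrame({
        "cr_max_diff": max_diff,
        "cr_variance": variance,
        "n_cell_lines_used": counts[keep].astype(int),
    })


def compare_groups(
    values: pd.Series | dict,
    group_a, group_b,
    alternative: str = "two-sided",
) -> RankSumResult:
    """Wilcoxon rank-sum comparison of a per-gene statistic between two
    disjoint gene sets (exact enumeration when both groups <= 8)."""
    values = pd.Series(values)
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    a = values.reindex(sorted(group_a)).dropna().to_numpy()
    b = values.reindex(sorted(group_b)).dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group after matching against values")
    return rank_sum_test(a, b, alternative=alternative)
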