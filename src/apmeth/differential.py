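"""Differential gene expression and differential promoter activity.

Genes: a paired two-sided t-test on log2(normalized count + 1) with a
DESeq2-style decision rule (p < 0.05 and |log2FC| > 1).  Promoters: one-way
ANOVA on absolute and relative activity between tumor and normal, with a
promoter called a differentially regulated promoter (DRP) when p < 0.05 and
the linear fold change of mean absolute activity exceeds 1.2.

No multiple-testing correction is applied by default, matching the raw
p < 0.05 rules used throughout; ``bh_correction=True`` switches the gene and
promoter p-values to Benjamini-Hochberg adjusted ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._design import condition_samples, paired_samples

__all__ = [
    "gene_differential",
    "promoter_fold_change",
    "promoter_anova",
    "group_anova_table",
    "call_drps",
    "promoter_differential",
    "DRP_FC_THRESHOLD",
]

DRP_FC_THRESHOLD = 1.2
GENE_EPS = 1.0
PROMOTER_EPS = 1e-3


def _bh(p: pd.Series) -> pd.Series:
    mask = p.notna()
    adj = p.copy()
    if mask.sum():
        adj[mask] = stats.false_discovery_control(p[mask], method="bh")
    return adj


def gene_differential(gene_counts: pd.DataFrame, design: pd.DataFrame,
                      bh_correction: bool = False) -> pd.DataFrame:
    """Per-gene tumor-vs-normal fold change and paired-test p-value.

    ``gene_counts`` is genes x samples of non-negative counts.  Counts are
    normalized by median-of-ratios size factors; log2FC uses a pseudo-count
    of 1 on the normalized means; p is a two-sided paired t-test on
    log2(normalized + 1), pairing by ``pair_id``.  Genes with all-zero
    counts get p = NA and are never DEGs.
    """
    from .activity import estimate_size_factors

    sf = estimate_size_factors(gene_counts)
    norm = gene_counts.div(sf, axis=1)
    tumor_s = condition_samples(design, "tumor")
    normal_s = condition_samples(design, "normal")
    if not tumor_s or not normal_s:
        raise ValueError("design must contain both tumor and normal samples")

    mean_t = norm[tumor_s].mean(axis=1)
    mean_n = norm[normal_s].mean(axis=1)
    log2_fc = np.log2((mean_t + GENE_EPS) / (mean_n + GENE_EPS))

    pt, pn = paired_samples(design)
    logv = np.log2(norm + 1.0)
    if len(pt) < 2:
        warnings.warn("fewer than 2 tumor/normal pairs: gene p-values are NA")
        p = pd.Series(np.nan, index=gene_counts.index)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(logv[pt].to_numpy(), logv[pn].to_numpy(),
                                  axis=1)
        p = pd.Series(res.pvalue, index=gene_counts.index)
    all_zero = (gene_counts.fillna(0) == 0).all(axis=1)
    p[all_zero] = np.nan
    if bh_correction:
        p = _bh(p)

    out = pd.DataFrame({
        "log2_fc": log2_fc,
        "p_value": p,
        "mean_norm_tumor": mean_t,
        "mean_norm_normal": mean_n,
    })
    out["is_deg"] = (out["p_value"] < 0.05) & (out["log2_fc"].abs() > 1.0)
    out["is_deg"] = out["is_deg"].fillna(False).astype(bool)
    out.index.name = "gene_id"
    return out


def promoter_fold_change(absolute: pd.DataFrame, design: pd.DataFrame,
                         eps: float = PROMOTER_EPS) -> pd.Series:
    """log2 of (mean tumor)/(mean normal) absolute activity.

    The means are taken on the absolute (log2) activity scale; a small
    pseudo-activity ``eps`` guards zero group means.
    """
    mean_t = absolute[condition_samples(design, "tumor")].mean(axis=1)
    mean_n = absolute[condition_samples(design, "normal")].mean(axis=1)
    fc = np.log2((mean_t + eps) / (mean_n + eps))
    fc.name = "log2_fc_abs"
    return fc


def promoter_anova(*groups) -> float:
    """One-way ANOVA p-value across groups of activity values.

    NAs are dropped; any group left with fewer than 2 values gives NA.  For
    two groups this is exactly the two-sided equal-variance t-test (F = t^2).
    Constant data carry no evidence against equal means: p = 1.
    """
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if len(clean) < 2 or any(len(g) < 2 for g in clean):
        return float("nan")
    pooled = np.concatenate(clean)
    if np.ptp(pooled) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.f_oneway(*clean)
    if not np.isfinite(p):
        if np.isinf(stat):
            return 0.0
        if np.isfinite(stat) and stat <= 0:
            # between-group sum of squares vanished up to rounding error
            return 1.0
        return float("nan")
    return float(p)


def group_anova_table(values: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Row-wise tumor-vs-normal ANOVA p-values for a promoters x samples matrix."""
    tumor_s = condition_samples(design, "tumor")
    normal_s = condition_samples(design, "normal")
    t = values[tumor_s].to_numpy(dtype=float)
    n = values[normal_s].to_numpy(dtype=float)
    p = np.array([promoter_anova(t[i], n[i]) for i in range(values.shape[0])])
    return pd.Series(p, index=values.index, name="p_anova")


def call_drps(table: pd.DataFrame, p_threshold: float = 0.05,
              fc_threshold: float = DRP_FC_THRESHOLD) -> pd.DataFrame:
    """Flag DRPs: p_abs < p_threshold and linear |FC| > fc_threshold."""
    out = table.copy()
    log2_thr = np.log2(fc_threshold)
    out["is_drp"] = ((out["p_abs"] < p_threshold)
                     & (out["log2_fc_abs"].abs() > log2_thr))
    out["is_drp"] = out["is_drp"].fillna(False).astype(bool)
    out["direction"] = np.where(
        ~out["is_drp"], "none",
        np.where(out["log2_fc_abs"] > 0, "up", "down"))
    return out


def promoter_differential(activity, design: pd.DataFrame,
                          bh_correction: bool = False,
                          p_threshold: float = 0.05,
                          fc_threshold: float = DRP_FC_THRESHOLD) -> pd.DataFrame:
    """Per-promoter differential table from an :class:`ActivityMatrix`.

    Columns: gene_id, mean absolute activity per condition, log2_fc_abs,
    p_abs (ANOVA on absolute activity), p_rel (ANOVA on relative activity),
    is_drp, direction.
    """
    absolute = activity.absolute
    tumor_s = condition_samples(design, "tumor")
    normal_s = condition_samples(design, "normal")
    table = pd.DataFrame({
        "gene_id": activity.gene_map.reindex(absolute.index),
        "mean_abs_tumor": absolute[tumor_s].mean(axis=1),
        "mean_abs_normal": absolute[normal_s].mean(axis=1),
        "log2_fc_abs": promoter_fold_change(absolute, design),
        "p_abs": group_anova_table(absolute, design),
        "p_rel": group_anova_table(activity.relative, design),
    })
    if bh_correction:
        table["p_abs"] = _bh(table["p_abs"])
        table["p_rel"] = _bh(table["p_rel"])
    table.index.name = "promoter_id"
    return call_drps(table, p_threshold, fc_threshold)
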