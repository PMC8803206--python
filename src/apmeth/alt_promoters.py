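"""Alternative promoter (AP) identification.

An AP is a promoter whose activity shifts between tumor and normal while the
gene's overall expression does not: the gene is non-differential (p >= 0.05
and linear |FC| < 2), the promoter is active in both groups (mean absolute
activity > 0.25), both absolute and relative activity change significantly
(p < 0.05), and the absolute-activity linear fold change exceeds 1.2.  Genes
carrying both an up- and a down-regulated AP are switch-usage genes: one
promoter is substituted for another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "APThresholds",
    "identify_aps",
    "find_switch_genes",
    "classify_isoform_association",
]


@dataclass(frozen=True)
class APThresholds:
    gene_p: float = 0.05          # gene must be NON-significant at this level
    gene_fc: float = 2.0          # linear gene |FC| must stay below
    activity_min: float = 0.25    # mean absolute activity in each group
    promoter_p: float = 0.05      # abs and rel activity ANOVA
    promoter_fc: float = 1.2      # linear |FC| of absolute activity


def identify_aps(gene_diff: pd.DataFrame, promoter_diff: pd.DataFrame,
                 thresholds: APThresholds = APThresholds()) -> pd.DataFrame:
    """Apply the four AP criteria as one conjunction, with a per-criterion log.

    ``gene_diff`` is indexed by gene_id (columns log2_fc, p_value);
    ``promoter_diff`` is indexed by promoter_id (columns gene_id,
    mean_abs_tumor, mean_abs_normal, p_abs, p_rel, log2_fc_abs).  Promoters
    of genes with NA gene p-values are ineligible and flagged in the
    ``gene_p_na`` column.  Returns the promoter table with boolean
    ``pass_gene``, ``pass_activity``, ``pass_significance``, ``pass_fc``,
    ``is_ap`` and a direction column.
    """
    thr = thresholds
    out = promoter_diff.copy()
    g = gene_diff.reindex(out["gene_id"])
    gene_p = pd.Series(g["p_value"].to_numpy(), index=out.index)
    gene_fc = pd.Series(g["log2_fc"].to_numpy(), index=out.index)

    out["gene_p_na"] = gene_p.isna()
    if out["gene_p_na"].any():
        warnings.warn(f"{int(out['gene_p_na'].sum())} promoter(s) ineligible: "
                      "gene p-value is NA")
    out["pass_gene"] = ((gene_p >= thr.gene_p)
                        & (gene_fc.abs() < np.log2(thr.gene_fc))).fillna(False)
    out["pass_activity"] = ((out["mean_abs_tumor"] > thr.activity_min)
                            & (out["mean_abs_normal"] > thr.activity_min))
    out["pass_significance"] = ((out["p_abs"] < thr.promoter_p)
                                & (out["p_rel"] < thr.promoter_p)).fillna(False)
    out["pass_fc"] = (out["log2_fc_abs"].abs()
                      > np.log2(thr.promoter_fc)).fillna(False)
    out["is_ap"] = (out["pass_gene"] & out["pass_activity"]
                    & out["pass_significance"] & out["pass_fc"])
    out["ap_direction"] = np.where(
        ~out["is_ap"], "none", np.where(out["log2_fc_abs"] > 0, "up", "down"))
    return out


def find_switch_genes(ap_table: pd.DataFrame) -> list[str]:
    """Genes with at least one up-regulated and one down-regulated AP."""
    aps = ap_table[ap_table["is_ap"]]
    per_gene = aps.groupby("gene_id")["ap_direction"].agg(set)
    return sorted(per_gene.index[per_gene.map(lambda s: {"up", "down"} <= s)])


def _pick_min_p(iso: pd.DataFrame) -> pd.Series:
    """Most significant isoform; ties by larger |FC|, then transcript id."""
    key = iso.assign(_absfc=iso["log2_fc"].abs())
    key = key.sort_values(["p_value", "_absfc", "transcript_id"],
                          ascending=[True, False, True], na_position="last")
    return key.iloc[0]


def _pick_max_fc(iso: pd.DataFrame) -> pd.Series:
    key = iso.assign(_absfc=iso["log2_fc"].abs())
    key = key.sort_values(["_absfc", "transcript_id"],
                          ascending=[False, True], na_position="last")
    return key.iloc[0]


def classify_isoform_association(ap_table: pd.DataFrame,
                                 member_transcripts: dict[str, tuple[str, ...]],
                                 isoform_diff: pd.DataFrame,
                                 p_threshold: float = 0.05,
                                 fc_threshold: float = 1.2) -> pd.Series:
    """Classify each AP by how its transcript isoforms respond.

    ``isoform_diff`` is indexed by transcript_id with columns log2_fc and
    p_value (computed like the gene differential, on transcript expression).
    Single-isoform APs: ``single_significant`` when the isoform changes
    significantly, else ``single_fc_only`` when its linear |FC| > 1.2, else
    ``single_neutral``.  Multi-isoform APs: ``multi_major_significant`` when
    the minimum-p isoform is significant, else ``multi_major_fc`` when the
    maximum-|FC| isoform exceeds 1.2-fold, else ``multi_other``.  APs whose
    isoform expression is missing get NA with a warning.
    """
    log2_thr = np.log2(fc_threshold)
    classes: dict[str, object] = {}
    missing = 0
    for pid in ap_table.index[ap_table["is_ap"]]:
        members = list(member_transcripts.get(pid, ()))
        iso = isoform_diff.reindex(members).dropna(subset=["log2_fc"])
        if iso.empty:
            classes[pid] = np.nan
            missing += 1
            continue
        iso = iso.reset_index().rename(columns={"index": "transcript_id"})
        if len(members) == 1:
            row = iso.iloc[0]
            if row["p_value"] < p_threshold:
                classes[pid] = "single_significant"
            elif abs(row["log2_fc"]) > log2_thr:
                classes[pid] = "single_fc_only"
            else:
                classes[pid] = "single_neutral"
        else:
            best_p = _pick_min_p(iso)
            if pd.notna(best_p["p_value"]) and best_p["p_value"] < p_threshold:
                classes[pid] = "multi_major_significant"
            elif abs(_pick_max_fc(iso)["log2_fc"]) > log2_thr:
                classes[pid] = "multi_major_fc"
            else:
                classes[pid] = "multi_other"
    if missing:
        warnings.warn(f"{missing} AP(s) lack isoform expression; class is NA")
    s = pd.Series(classes, dtype=object, name="isoform_class")
    s.index.name = "promoter_id"
    return s
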