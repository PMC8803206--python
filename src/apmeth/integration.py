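"""Coupling promoter-activity change to methylation change.

Promoters are classified by the sign of the significant methylation-activity
correlation at their representative CpG; APs with a negative correlation are
methylation-regulated APs (mrAPs).  Group-level coupling is the Pearson
correlation between the representative-CpG delta beta and the promoter's
log2 activity fold change, restricted to promoters with a substantial
methylation change (|delta beta| > 0.1 by default, 0.2 in strict mode).
Cross-dataset concordance confirms activity changes (>= 1.2-fold in the same
direction in at least one validation pair) and methylation changes (same-sign
delta > 0.1 at the same CpG, falling back to the +-1 kb region mean).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._design import paired_samples
from .methylation import (MethylationMatrix, pearson, promoter_region_mean,
                          REPRESENTATIVE_WINDOW)

__all__ = [
    "classify_correlation",
    "call_mraps",
    "group_correlation_test",
    "integrate",
    "confirm_activity_change",
    "confirm_methylation_change",
    "concordance_summary",
]

METH_DELTA = 0.1
METH_DELTA_STRICT = 0.2


def classify_correlation(links: pd.DataFrame,
                         p_threshold: float = 0.05) -> pd.Series:
    """negative / positive / none per promoter from its representative CpG.

    ``negative`` iff p < threshold and r < 0; ``positive`` iff p < threshold
    and r > 0; anything else (including undefined correlations) is ``none``.
    """
    sig = links["p"] < p_threshold
    cls = np.where(sig & (links["r"] < 0), "negative",
                   np.where(sig & (links["r"] > 0), "positive", "none"))
    return pd.Series(cls, index=links.index, name="corr_class")


def call_mraps(ap_ids, corr_class: pd.Series) -> set[str]:
    """mrAPs: APs whose representative-CpG correlation class is negative."""
    negative = set(corr_class.index[corr_class == "negative"])
    return set(ap_ids) & negative


def group_correlation_test(delta_meth: pd.Series, norm_fc: pd.Series,
                           meth_delta: float = METH_DELTA
                           ) -> tuple[float, float]:
    """Pearson (R, p) between delta beta and activity log2FC.

    Only promoters with |delta beta| > ``meth_delta`` enter; fewer than 3
    qualifying promoters gives (NA, NA).
    """
    df = pd.DataFrame({"d": delta_meth, "f": norm_fc}).dropna()
    df = df[df["d"].abs() > meth_delta]
    if len(df) < 3:
        return (float("nan"), float("nan"))
    return pearson(df["d"].to_numpy(), df["f"].to_numpy())


def integrate(promoter_diff: pd.DataFrame, ap_table: pd.DataFrame,
              links: pd.DataFrame,
              meth_delta: float = METH_DELTA) -> pd.DataFrame:
    """Per-promoter integration record over promoters with a representative CpG.

    Columns: norm_fc (log2 activity FC), delta_meth, passes_meth_change,
    corr_class, is_drp, is_ap, is_mrap.  Promoters without a link are
    excluded (they cannot be classified), which also defines the denominator
    of the correlation-class proportions.
    """
    idx = links.index.intersection(promoter_diff.index)
    corr_class = classify_correlation(links.loc[idx])
    out = pd.DataFrame({
        "norm_fc": promoter_diff.loc[idx, "log2_fc_abs"],
        "delta_meth": links.loc[idx, "delta_beta"],
        "corr_class": corr_class,
        "is_drp": promoter_diff.loc[idx, "is_drp"],
        "is_ap": ap_table.loc[idx, "is_ap"] if "is_ap" in ap_table else False,
    })
    out["passes_meth_change"] = out["delta_meth"].abs() > meth_delta
    mraps = call_mraps(set(out.index[out["is_ap"]]), corr_class)
    out["is_mrap"] = out.index.isin(mraps)
    out.index.name = "promoter_id"
    return out


def confirm_activity_change(reference_fc: pd.Series,
                            validation_absolute: pd.DataFrame,
                            validation_design: pd.DataFrame,
                            fc_threshold: float = 1.2) -> pd.Series:
    """Confirm reference activity changes in a validation cohort.

    A promoter is ``confirmed`` when, in at least one validation tumor/normal
    pair, its linear activity ratio (activity taken as 2^absolute - 1)
    exceeds ``fc_threshold`` in the reference direction; ``untestable`` when
    absent from the validation matrix.
    """
    tumor, normal = paired_samples(validation_design)
    if not tumor:
        raise ValueError("validation design has no tumor/normal pair")
    eps = 1e-8
    linear = 2.0 ** validation_absolute - 1.0
    status = {}
    for pid, ref in reference_fc.items():
        if pid not in linear.index or not np.isfinite(ref):
            status[pid] = "untestable"
            continue
        ratios = ((linear.loc[pid, tumor].to_numpy() + eps)
                  / (linear.loc[pid, normal].to_numpy() + eps))
        if ref > 0:
            ok = bool((ratios > fc_threshold).any())
        else:
            ok = bool((ratios < 1.0 / fc_threshold).any())
        status[pid] = "confirmed" if ok else "not_confirmed"
    s = pd.Series(status, name="activity_status")
    s.index.name = "promoter_id"
    return s


def confirm_methylation_change(reference_delta: float,
                               probe_chrom: str, probe_pos: int,
                               validation_meth: MethylationMatrix,
                               promoter, validation_design: pd.DataFrame,
                               meth_delta: float = METH_DELTA,
                               window: int = REPRESENTATIVE_WINDOW) -> str:
    """Confirm one reference CpG delta beta against validation methylation.

    Tests the same CpG position in the validation data; when the site lacks
    data, falls back to the +-window promoter-region mean restricted to CpGs
    covered in all validation samples.  ``confirmed`` iff the validation
    delta exceeds ``meth_delta`` in magnitude with the reference sign;
    ``untestable`` when neither the site nor the region can be evaluated.
    """
    if not np.isfinite(reference_delta):
        return "untestable"
    from .methylation import delta_beta

    val_delta = np.nan
    probe = validation_meth.locate(probe_chrom, probe_pos)
    if probe is not None:
        val_delta = delta_beta(validation_meth, validation_design).loc[probe]
    if not np.isfinite(val_delta):
        region = promoter_region_mean(validation_meth, promoter, window=window,
                                      require_full_coverage=True)
        region = region.to_frame("beta")
        d = delta_beta(
            MethylationMatrix(probes=pd.DataFrame(), beta=region.T),
            validation_design,
        )
        val_delta = d.iloc[0] if len(d) else np.nan
    if not np.isfinite(val_delta):
        return "untestable"
    same_sign = np.sign(val_delta) == np.sign(reference_delta)
    return ("confirmed" if abs(val_delta) > meth_delta and same_sign
            else "not_confirmed")


def concordance_summary(statuses: pd.Series) -> dict[str, float]:
    """Counts and the confirmed percentage among testable promoters."""
    counts = statuses.value_counts().to_dict()
    confirmed = counts.get("confirmed", 0)
    testable = confirmed + counts.get("not_confirmed", 0)
    return {
        "confirmed": int(confirmed),
        "not_confirmed": int(counts.get("not_confirmed", 0)),
        "untestable": int(counts.get("untestable", 0)),
        "pct_confirmed": (100.0 * confirmed / testable if testable else
                          float("nan")),
    }
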