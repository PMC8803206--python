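"""Sample design-table handling shared across modules."""

from __future__ import annotations

import pandas as pd

CONDITIONS = ("tumor", "normal")


def normalize_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and index a design table by sample_id.

    Expected columns: sample_id (or index), condition in {tumor, normal},
    pair_id.  Extra columns (e.g. sj_path) pass through untouched.
    """
    df = design.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if "condition" not in df.columns:
        raise ValueError("design table lacks a 'condition' column")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    return df


def condition_samples(design: pd.DataFrame, condition: str) -> list[str]:
    df = normalize_design(design)
    return list(df.index[df["condition"] == condition])


def paired_samples(design: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Tumor and normal sample ids ordered by shared pair_id.

    Only pairs with exactly one tumor and one normal sample are used.
    """
    df = normalize_design(design)
    if "pair_id" not in df.columns:
        raise ValueError("design table lacks a 'pair_id' column")
    tumor, normal = [], []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        t = grp.index[grp["condition"] == "tumor"]
        n = grp.index[grp["condition"] == "normal"]
        if len(t) == 1 and len(n) == 1:
            tumor.append(t[0])
            normal.append(n[0])
    return tumor, normal
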