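"""Promoter activity from splice-junction counts.

A promoter's raw activity in a sample is the sum of unique junction reads
whose splice-donor coordinate matches one of the promoter's first-exon donor
sites (strand-aware exact match).  Raw counts are normalized by
median-of-ratios size factors; absolute activity is log2(normalized + 1) and
relative activity is a promoter's share of the summed absolute activity of
its gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import PromoterAnnotation

__all__ = [
    "ActivityMatrix",
    "read_junction_table",
    "count_promoter_reads",
    "estimate_size_factors",
    "absolute_activity",
    "relative_activity",
    "filter_promoters",
    "promoter_activity",
]

_SJ_COLUMNS = ["chrom", "intron_start", "intron_end", "strand_code",
               "motif", "annotated", "unique_reads", "multi_reads",
               "max_overhang"]
_STRAND_CODE = {0: ".", 1: "+", 2: "-"}


@dataclass
class ActivityMatrix:
    """Raw and normalized promoter activity (promoters x samples).

    ``absolute`` is on the log2(normalized + 1) scale; ``relative`` rows of a
    gene sum to 1 wherever ``gene_absolute`` is positive and are NA where it
    is zero.
    """

    raw_counts: pd.DataFrame
    size_factors: pd.Series
    absolute: pd.DataFrame
    relative: pd.DataFrame
    gene_absolute: pd.DataFrame
    gene_map: pd.Series
    removal_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["promoter_id", "reason"])
    )

    @property
    def samples(self) -> list[str]:
        return list(self.raw_counts.columns)


def read_junction_table(path) -> pd.DataFrame:
    """Read one STAR ``SJ.out.tab`` file.

    Nine whitespace-separated columns; only unique-read counts (column 7)
    are retained.  1-based inclusive intron coordinates become 0-based
    half-open; strand code 0 (undefined) is kept with strand ".".  Returns a
    DataFrame with columns chrom, start, end, strand, count.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                         comment=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "count"])
    if df.shape[1] != 9:
        raise ValueError(f"{path}: expected 9 columns, found {df.shape[1]}")
    df.columns = _SJ_COLUMNS
    numeric = df[_SJ_COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 1}")
    strand_ok = numeric["strand_code"].isin(_STRAND_CODE)
    if not strand_ok.all():
        raise ValueError(
            f"{path}: invalid strand code at line {int((~strand_ok).idxmax()) + 1}"
        )
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": numeric["intron_start"].astype(int) - 1,
        "end": numeric["intron_end"].astype(int),
        "strand": numeric["strand_code"].map(_STRAND_CODE),
        "count": numeric["unique_reads"].astype(int),
    })
    if (out["start"] >= out["end"]).any():
        row = int((out["start"] >= out["end"]).idxmax())
        raise ValueError(f"{path}: intron start >= end at line {row + 1}")
    if (out["count"] < 0).any():
        row = int((out["count"] < 0).idxmax())
        raise ValueError(f"{path}: negative unique-read count at line {row + 1}")
    return out


def _donor_keys(junctions: pd.DataFrame) -> pd.DataFrame:
    """Expand junctions into (chrom, strand, donor, count) rows.

    The donor coordinate is the intron 5' end in transcription direction:
    the 0-based intron start on '+', the half-open intron end on '-'.
    Strand "." junctions are tried on both strands.
    """
    parts = []
    for strand, donor_col in (("+", "start"), ("-", "end")):
        sub = junctions[junctions["strand"].isin([strand, "."])]
        if len(sub):
            parts.append(pd.DataFrame({
                "chrom": sub["chrom"].to_numpy(),
                "strand": strand,
                "donor": sub[donor_col].to_numpy(),
                "count": sub["count"].to_numpy(),
            }))
    if not parts:
        return pd.DataFrame(columns=["chrom", "strand", "donor", "count"])
    return pd.concat(parts, ignore_index=True)


def count_promoter_reads(junctions: dict[str, pd.DataFrame],
                         catalog: PromoterAnnotation) -> pd.DataFrame:
    """Promoter x sample matrix of unique junction reads at donor sites.

    ``junctions`` maps sample id to a table from :func:`read_junction_table`.
    Junctions matching no promoter are ignored; junction input order is
    irrelevant.
    """
    donor_index = catalog.donor_index()
    cols = {}
    for sample, table in junctions.items():
        keys = _donor_keys(table)
        merged = keys.merge(donor_index, on=["chrom", "strand", "donor"],
                            how="inner")
        counts = merged.groupby("promoter_id")["count"].sum()
        cols[sample] = counts
    raw = pd.DataFrame(cols, columns=list(junctions), dtype=float).reindex(
        catalog.promoter_ids).fillna(0).astype(int)
    raw.index.name = "promoter_id"
    return raw


def estimate_size_factors(raw_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Rows containing any zero are excluded from the reference geometric
    means.  If no all-positive row exists the estimator degenerates and we
    fall back to total-count ratios, normalized so their log-mean is zero.
    """
    if raw_counts.shape[1] < 2:
        raise ValueError("size-factor estimation needs at least 2 samples")
    positive = raw_counts[(raw_counts > 0).all(axis=1)]
    if len(positive) == 0:
        warnings.warn("no promoter with all-positive counts; "
                      "falling back to total-count normalization")
        totals = raw_counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValueError("cannot normalize: a sample has zero total counts")
        sf = totals / np.exp(np.log(totals).mean())
    else:
        log_geomean = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geomean, axis=0)
        sf = np.exp(ratios.median(axis=0))
    sf.name = "size_factor"
    return sf


def absolute_activity(raw_counts: pd.DataFrame,
                      size_factors: pd.Series) -> pd.DataFrame:
    """log2(raw / size_factor + 1), the absolute promoter activity scale."""
    return np.log2(raw_counts.div(size_factors, axis=1) + 1.0)


def relative_activity(absolute: pd.DataFrame, gene_map: pd.Series
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-promoter share of summed gene activity, plus the gene totals.

    Returns ``(relative, gene_absolute)``.  ``relative`` is NA for all
    promoters of a gene in samples where the gene total is zero.
    """
    genes = gene_map.reindex(absolute.index)
    gene_absolute = absolute.groupby(genes).sum()
    gene_absolute.index.name = "gene_id"
    denom = gene_absolute.reindex(genes.to_numpy())
    denom.index = absolute.index
    relative = absolute / denom.where(denom > 0)
    return relative, gene_absolute


def filter_promoters(raw_counts: pd.DataFrame, catalog: PromoterAnnotation,
                     design: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the promoter filters before activity estimation.

    Drops (a) promoters whose member transcripts are all single-exon (no
    junction evidence exists for them) and (b) promoters whose raw counts are
    zero or NA in every tumor AND every normal sample.  Returns the filtered
    count matrix and a removal log with one row per dropped promoter.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    unmatched = [s for s in raw_counts.columns if s not in design.index]
    if unmatched:
        raise ValueError("samples missing from design table: "
                         + ", ".join(map(str, unmatched)))

    removals = []
    single = {p.promoter_id for p in catalog if p.is_single_exon_only}
    for pid in raw_counts.index:
        if pid in single:
            removals.append((pid, "single_exon_only"))

    signal = raw_counts.fillna(0) > 0
    no_signal = ~signal.any(axis=1)
    for pid in raw_counts.index[no_signal]:
        if pid not in single:
            removals.append((pid, "no_signal"))

    log = pd.DataFrame(removals, columns=["promoter_id", "reason"])
    kept = raw_counts.drop(index=log["promoter_id"].tolist())
    return kept, log


def promoter_activity(junctions: dict[str, pd.DataFrame],
                      catalog: PromoterAnnotation,
                      design: pd.DataFrame) -> ActivityMatrix:
    """Count, filter and normalize: the full activity-estimation step."""
    raw = count_promoter_reads(junctions, catalog)
    raw, removal_log = filter_promoters(raw, catalog, design)
    sf = estimate_size_factors(raw)
    absolute = absolute_activity(raw, sf)
    gene_map = catalog.gene_map()
    relative, gene_absolute = relative_activity(absolute, gene_map)
    return ActivityMatrix(
        raw_counts=raw,
        size_factors=sf,
        absolute=absolute,
        relative=relative,
        gene_absolute=gene_absolute,
        gene_map=gene_map.reindex(raw.index),
        removal_log=removal_log,
    )
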