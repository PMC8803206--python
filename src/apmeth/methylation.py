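"""CpG methylation: 450K-style beta matrices, WGBS ratios, and their
relationship to promoter TSSs.

Betas are fractions methylated in [0, 1].  Distances to a promoter TSS are
signed in transcription direction (negative = upstream).  The representative
CpG of a promoter is the CpG within +-1 kb of the TSS whose methylation is
most significantly Pearson-correlated with the promoter's absolute activity
across samples (tumor and normal pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import condition_samples
from .gene_models import Promoter, PromoterAnnotation

__all__ = [
    "MethylationMatrix",
    "CpGPromoterLink",
    "read_beta_matrix",
    "read_wgbs_ratios",
    "wgbs_cohort",
    "delta_beta",
    "pearson",
    "signed_tss_distance",
    "select_representative_cpg",
    "representative_cpgs",
    "tss_methylation_profile",
    "activity_quartile_profiles",
    "promoter_region_mean",
]

REPRESENTATIVE_WINDOW = 1000
PROFILE_SPAN = 2000
PROFILE_WIDTH = 50
PROFILE_STEP = 25


@dataclass
class MethylationMatrix:
    """Located CpG methylation values.

    ``probes``: DataFrame indexed by probe_id with columns chrom and pos
    (0-based point coordinate of the CpG cytosine on the forward strand).
    ``beta``: probes x samples in [0, 1] or NA.  ``source`` is "array" or
    "wgbs"; WGBS matrices may carry per-probe coverage.
    """

    probes: pd.DataFrame
    beta: pd.DataFrame
    source: str = "array"
    coverage: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def locate(self, chrom: str, pos: int) -> str | None:
        hit = self.probes.index[(self.probes["chrom"] == chrom)
                                & (self.probes["pos"] == pos)]
        return hit[0] if len(hit) else None


@dataclass(frozen=True)
class CpGPromoterLink:
    """Representative CpG of a promoter with its correlation statistics."""

    promoter_id: str
    probe_id: str
    dist_to_tss: int
    r: float
    p: float
    delta_beta: float = float("nan")


def read_beta_matrix(matrix, manifest) -> MethylationMatrix:
    """Join a probe x sample beta TSV with a probe manifest.

    The manifest has columns probe_id, chrom, pos (1-based; converted to
    0-based).  Probes absent from the manifest are dropped with a warning;
    duplicate probe ids or betas outside [0, 1] (beyond 1e-6) are errors.
    """
    beta = matrix if isinstance(matrix, pd.DataFrame) else pd.read_csv(
        matrix, sep="\t", index_col=0)
    man = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(
        manifest, sep="\t")
    if beta.index.duplicated().any() or man["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids")
    man = man.set_index("probe_id")

    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(finite) and (finite.min() < -1e-6 or finite.max() > 1 + 1e-6):
        raise ValueError("beta values outside [0, 1]")
    beta = beta.clip(0.0, 1.0)

    located = beta.index.intersection(man.index)
    dropped = len(beta.index) - len(located)
    if dropped:
        warnings.warn(f"{dropped} probe(s) missing from manifest; dropped")
    probes = pd.DataFrame({
        "chrom": man.loc[located, "chrom"],
        "pos": man.loc[located, "pos"].astype(int) - 1,
    })
    probes.index.name = "probe_id"
    return MethylationMatrix(probes=probes, beta=beta.loc[located],
                             source="array")


def read_wgbs_ratios(path, sample_id: str = "sample") -> MethylationMatrix:
    """Read a bedGraph-like per-CpG methylation ratio file.

    Columns: chrom, start (0-based), end, ratio, optional coverage.  One
    probe per CpG position, probe_id synthesized as ``chrom:pos``.
    Duplicated positions and ratios outside [0, 1] are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] not in (4, 5):
        raise ValueError(f"{path}: expected 4 or 5 columns, found {df.shape[1]}")
    df.columns = ["chrom", "start", "end", "ratio", "coverage"][: df.shape[1]]
    bad = (df["ratio"] < 0) | (df["ratio"] > 1)
    if bad.any():
        raise ValueError(f"{path}: ratio outside [0, 1] at line "
                         f"{int(bad.idxmax()) + 1}")
    if df.duplicated(subset=["chrom", "start"]).any():
        dup = df[df.duplicated(subset=["chrom", "start"])].iloc[0]
        raise ValueError(f"{path}: duplicated CpG position "
                         f"{dup['chrom']}:{dup['start']}")
    ids = df["chrom"].astype(str) + ":" + df["start"].astype(str)
    probes = pd.DataFrame({"chrom": df["chrom"].to_numpy(),
                           "pos": df["start"].astype(int).to_numpy()},
                          index=pd.Index(ids, name="probe_id"))
    beta = pd.DataFrame({sample_id: df["ratio"].to_numpy()}, index=probes.index)
    coverage = None
    if "coverage" in df.columns:
        coverage = pd.DataFrame({sample_id: df["coverage"].to_numpy()},
                                index=probes.index)
    return MethylationMatrix(probes=probes, beta=beta, source="wgbs",
                             coverage=coverage)


def wgbs_cohort(paths_by_sample: dict[str, object]) -> MethylationMatrix:
    """Combine per-sample WGBS ratio files into one matrix (outer join on CpG)."""
    singles = {s: read_wgbs_ratios(p, sample_id=s)
               for s, p in paths_by_sample.items()}
    probes = pd.concat([m.probes for m in singles.values()])
    probes = probes[~probes.index.duplicated()]
    beta = pd.concat([m.beta.reindex(probes.index) for m in singles.values()],
                     axis=1)
    return MethylationMatrix(probes=probes, beta=beta, source="wgbs")


def delta_beta(meth: MethylationMatrix, design: pd.DataFrame) -> pd.Series:
    """Per-probe mean(tumor) - mean(normal) beta; positive = tumor hypermethylation.

    NAs are excluded per group; a probe with no data in either group is NA.
    """
    tumor = meth.beta[condition_samples(design, "tumor")]
    normal = meth.beta[condition_samples(design, "normal")]
    d = tumor.mean(axis=1, skipna=True) - normal.mean(axis=1, skipna=True)
    d.name = "delta_beta"
    return d


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    Needs >= 3 paired finite values and non-constant vectors; otherwise
    returns (NA, NA).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def signed_tss_distance(pos, tss: int, strand: str):
    """Signed bp distance of CpG positions to a TSS; negative = upstream."""
    d = np.asarray(pos) - tss
    return d if strand == "+" else -d


def _window_probes(meth: MethylationMatrix, promoter: Promoter,
                   window: int) -> pd.DataFrame:
    """Probes within +-window of the promoter TSS (inclusive), with distances."""
    sub = meth.probes[meth.probes["chrom"] == promoter.chrom]
    dist = signed_tss_distance(sub["pos"].to_numpy(), promoter.tss,
                               promoter.strand)
    keep = np.abs(dist) <= window
    out = sub[keep].copy()
    out["dist_to_tss"] = dist[keep]
    return out


def select_representative_cpg(promoter: Promoter, meth: MethylationMatrix,
                              activity: pd.Series,
                              design: pd.DataFrame | None = None,
                              window: int = REPRESENTATIVE_WINDOW
                              ) -> CpGPromoterLink | None:
    """Minimum-correlation-p CpG within +-window of the promoter TSS.

    ``activity`` is the promoter's absolute activity per sample; beta and
    activity are paired over shared samples (tumor + normal pooled).  Ties on
    p are broken by smaller |distance|, then probe_id.  Returns None when no
    CpG lies in the window or every candidate correlation is undefined.
    When ``design`` is given the link carries the probe's delta beta.
    """
    cands = _window_probes(meth, promoter, window)
    if cands.empty:
        return None
    samples = [s for s in meth.samples if s in activity.index]
    act = activity[samples].to_numpy(dtype=float)
    best = None
    for probe_id, row in cands.iterrows():
        r, p = pearson(meth.beta.loc[probe_id, samples].to_numpy(), act)
        if np.isnan(p):
            continue
        key = (p, abs(int(row["dist_to_tss"])), probe_id)
        if best is None or key < best[0]:
            best = (key, probe_id, int(row["dist_to_tss"]), r, p)
    if best is None:
        warnings.warn(f"{promoter.promoter_id}: all candidate correlations "
                      "undefined")
        return None
    _, probe_id, dist, r, p = best
    db = float("nan")
    if design is not None:
        db = float(delta_beta(meth, design).loc[probe_id])
    return CpGPromoterLink(promoter_id=promoter.promoter_id, probe_id=probe_id,
                           dist_to_tss=dist, r=r, p=p, delta_beta=db)


def representative_cpgs(catalog: PromoterAnnotation, meth: MethylationMatrix,
                        absolute: pd.DataFrame,
                        design: pd.DataFrame | None = None,
                        promoter_ids=None,
                        window: int = REPRESENTATIVE_WINDOW) -> pd.DataFrame:
    """Representative-CpG link table for a set of promoters."""
    if promoter_ids is None:
        promoter_ids = [p for p in catalog.promoter_ids if p in absolute.index]
    db = delta_beta(meth, design) if design is not None else None
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid in promoter_ids:
            link = select_representative_cpg(catalog[pid], meth,
                                             absolute.loc[pid], window=window)
            if link is None:
                continue
            rows.append({
                "promoter_id": pid,
                "probe_id": link.probe_id,
                "dist_to_tss": link.dist_to_tss,
                "r": link.r,
                "p": link.p,
                "delta_beta": (float(db.loc[link.probe_id])
                               if db is not None else float("nan")),
            })
    out = pd.DataFrame(rows, columns=["promoter_id", "probe_id", "dist_to_tss",
                                      "r", "p", "delta_beta"])
    return out.set_index("promoter_id")


def tss_methylation_profile(meth: MethylationMatrix,
                            promoters, samples,
                            span: int = PROFILE_SPAN,
                            width: int = PROFILE_WIDTH,
                            step: int = PROFILE_STEP) -> pd.DataFrame:
    """Sliding-window mean beta around the TSS, pooled over promoters.

    Windows of ``width`` bp advance by ``step`` bp across [-span, +span]
    (endpoints inclusive); each window averages all (probe, sample) betas of
    probes whose signed TSS distance falls inside it.  Windows without
    probes are NA.
    """
    promoters = list(promoters)
    records_d: list[np.ndarray] = []
    records_b: list[np.ndarray] = []
    for p in promoters:
        cands = _window_probes(meth, p, span + width)
        if cands.empty:
            continue
        b = meth.beta.loc[cands.index, list(samples)].to_numpy(dtype=float)
        records_d.append(np.repeat(cands["dist_to_tss"].to_numpy(), b.shape[1]))
        records_b.append(b.ravel())
    dists = (np.concatenate(records_d) if records_d else np.empty(0))
    betas = (np.concatenate(records_b) if records_b else np.empty(0))

    starts = np.arange(-span, span - width + 1, step)
    rows = []
    for s in starts:
        mask = (dists >= s) & (dists <= s + width)
        vals = betas[mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "window_start": int(s),
            "midpoint": int(s + width // 2),
            "mean_beta": float(np.mean(vals)) if len(vals) else float("nan"),
            "n_probes": int(mask.sum()),
        })
    return pd.DataFrame(rows)


def activity_quartile_profiles(activity_means: pd.Series,
                               meth: MethylationMatrix,
                               catalog: PromoterAnnotation,
                               samples, **profile_kw) -> dict[int, pd.DataFrame]:
    """TSS profiles for promoters split into activity quartiles (Q1 lowest).

    Promoters are ordered by (mean activity, promoter_id) — the tie rule —
    and split at the 25/50/75 percentiles by rank.  Requires >= 4 promoters.
    """
    if len(activity_means) < 4:
        raise ValueError("activity-quartile profiles need >= 4 promoters")
    order = activity_means.to_frame("act").assign(pid=activity_means.index)
    order = order.sort_values(["act", "pid"]).index
    n = len(order)
    profiles = {}
    for q in range(4):
        ids = [order[i] for i in range(n) if min(3, (4 * i) // n) == q]
        proms = [catalog[p] for p in ids]
        profiles[q + 1] = tss_methylation_profile(meth, proms, samples,
                                                  **profile_kw)
    return profiles


def promoter_region_mean(meth: MethylationMatrix, promoter: Promoter,
                         window: int = REPRESENTATIVE_WINDOW,
                         require_full_coverage: bool = False) -> pd.Series:
    """Per-sample mean beta of CpGs within +-window of the promoter TSS.

    With ``require_full_coverage`` only CpGs observed (non-NA) in every
    sample contribute.  All-NA when no CpG qualifies.
    """
    cands = _window_probes(meth, promoter, window)
    if cands.empty:
        return pd.Series(np.nan, index=meth.samples)
    b = meth.beta.loc[cands.index]
    if require_full_coverage:
        b = b[b.notna().all(axis=1)]
    return b.mean(axis=0, skipna=True)
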