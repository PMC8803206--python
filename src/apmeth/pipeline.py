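"""End-to-end orchestration: file-based stages and an in-memory analyzer.

Each stage reads the previous stage's TSV artifacts from the output
directory and writes its own, so stages are independently invokable and
``run_pipeline`` is exactly their composition.  :func:`analyze` performs the
same analysis on in-memory objects and returns an :class:`AnalysisResult`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._design import condition_samples, normalize_design
from .activity import ActivityMatrix, promoter_activity, read_junction_table
from .alt_promoters import (APThresholds, classify_isoform_association,
                            find_switch_genes, identify_aps)
from .clinical import (fit_diagnostic, flag_prognostic_mraps, roc_auc,
                       score_samples, HORIZON_YEARS, MINPROP)
from .differential import gene_differential, promoter_differential
from .gene_models import (PromoterAnnotation, build_promoters,
                          flag_internal_promoters, parse_gene_models)
from .integration import (METH_DELTA, concordance_summary, group_correlation_test,
                          integrate)
from .methylation import MethylationMatrix, read_beta_matrix, representative_cpgs

__all__ = ["PipelineConfig", "AnalysisResult", "analyze", "run_pipeline",
           "STAGES"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and model settings for a pipeline run."""

    gtf: str = ""
    design: str = ""
    beta_matrix: str = ""
    manifest: str = ""
    cohort_beta: str = ""
    clinical: str = ""
    gene_counts: str = ""
    isoform_expression: str = ""
    thresholds: APThresholds = field(default_factory=APThresholds)
    meth_delta: float = METH_DELTA
    folds: int = 10
    seed: int = 0
    minprop: float = MINPROP
    horizon: float = HORIZON_YEARS
    bh_correction: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("thresholds", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if thr:
            cfg.thresholds = APThresholds(**thr)
        return cfg

    def validate(self) -> None:
        for name in ("gtf", "design"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path '{name}' missing: {p!r}")


@dataclass
class AnalysisResult:
    catalog: PromoterAnnotation
    activity: ActivityMatrix
    gene_diff: pd.DataFrame
    promoter_diff: pd.DataFrame
    ap_table: pd.DataFrame
    switch_genes: list[str]
    links: pd.DataFrame | None = None
    integration: pd.DataFrame | None = None
    group_correlations: dict = field(default_factory=dict)
    mraps: set = field(default_factory=set)
    diagnostic: object = None
    scores: pd.Series | None = None
    auc: float = float("nan")
    survival: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def _read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                              "pair_id": str})


def read_clinical(path) -> pd.DataFrame:
    """Clinical table with sample_id, a declared time column, and event.

    Time is taken from ``time``/``os_years`` (years) or ``os_days``
    (converted to years), so the 10-year horizon applies uniformly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "time" in df.columns or "os_years" in df.columns:
        df["time"] = df.get("time", df.get("os_years"))
    elif "os_days" in df.columns:
        df["time"] = df["os_days"] / 365.25
    else:
        raise ValueError("clinical table needs a time/os_years/os_days column")
    return df[["sample_id", "time", "event"]]


def analyze(catalog: PromoterAnnotation, junctions: dict[str, pd.DataFrame],
            design: pd.DataFrame,
            meth: MethylationMatrix | None = None,
            cohort_beta: pd.DataFrame | None = None,
            clinical: pd.DataFrame | None = None,
            gene_counts: pd.DataFrame | None = None,
            isoform_expression: pd.DataFrame | None = None,
            thresholds: APThresholds = APThresholds(),
            meth_delta: float = METH_DELTA,
            folds: int = 10, seed: int = 0,
            minprop: float = MINPROP, horizon: float = HORIZON_YEARS,
            bh_correction: bool = False) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    Methylation, diagnostic and survival stages run only when their inputs
    are provided.  ``gene_counts`` defaults to promoter counts summed per
    gene, so the gene-level test and the promoter filters see the same
    library.
    """
    activity = promoter_activity(junctions, catalog, design)
    if gene_counts is None:
        gene_counts = activity.raw_counts.groupby(activity.gene_map).sum()
    gene_diff = gene_differential(gene_counts, design,
                                  bh_correction=bh_correction)
    promoter_diff = promoter_differential(activity, design,
                                          bh_correction=bh_correction,
                                          p_threshold=thresholds.promoter_p,
                                          fc_threshold=thresholds.promoter_fc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap_table = identify_aps(gene_diff, promoter_diff, thresholds)
    if isoform_expression is not None:
        iso_diff = gene_differential(isoform_expression, design,
                                     bh_correction=bh_correction)
        iso_diff = iso_diff.rename(columns={"log2_fc": "log2_fc",
                                            "p_value": "p_value"})
        members = {p.promoter_id: p.member_transcripts for p in catalog}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap_table["isoform_class"] = classify_isoform_association(
                ap_table, members, iso_diff,
                p_threshold=thresholds.promoter_p,
                fc_threshold=thresholds.promoter_fc)
    switch_genes = find_switch_genes(ap_table)

    result = AnalysisResult(catalog=catalog, activity=activity,
                            gene_diff=gene_diff, promoter_diff=promoter_diff,
                            ap_table=ap_table, switch_genes=switch_genes)

    if meth is not None:
        drp_or_ap = promoter_diff.index[(promoter_diff["is_drp"])
                                        | ap_table["is_ap"]]
        result.links = representative_cpgs(catalog, meth, activity.absolute,
                                           design,
                                           promoter_ids=list(drp_or_ap))
        result.integration = integrate(promoter_diff, ap_table, result.links,
                                       meth_delta=meth_delta)
        result.mraps = set(
            result.integration.index[result.integration["is_mrap"]])
        for name, col in (("DRP", "is_drp"), ("AP", "is_ap"),
                          ("mrAP", "is_mrap")):
            sub = result.integration[result.integration[col]]
            r, p = group_correlation_test(sub["delta_meth"], sub["norm_fc"],
                                          meth_delta=meth_delta)
            result.group_correlations[name] = {"R": r, "p": p,
                                               "n": int(len(sub))}

        features = sorted(result.mraps)
        if len(features) >= 1:
            X = activity.absolute.loc[features].T
            labels = normalize_design(design)["condition"].reindex(X.index)
            result.diagnostic = fit_diagnostic(X, labels, folds=folds,
                                               seed=seed)
            result.scores = score_samples(result.diagnostic, X)
            result.auc = roc_auc(result.scores.to_numpy(), labels.to_numpy())

        if clinical is not None and cohort_beta is not None and result.mraps:
            mrap_links = result.links.loc[sorted(result.mraps)]
            result.survival = flag_prognostic_mraps(mrap_links, cohort_beta,
                                                    clinical, minprop=minprop,
                                                    horizon=horizon)

    result.summary = _summarize(result)
    return result


def _summarize(res: AnalysisResult) -> dict:
    n_drp = int(res.promoter_diff["is_drp"].sum())
    drpg = res.promoter_diff.loc[res.promoter_diff["is_drp"], "gene_id"]
    summary = {
        "n_promoters": int(len(res.activity.raw_counts)),
        "n_genes": int(res.gene_diff.shape[0]),
        "n_degs": int(res.gene_diff["is_deg"].sum()),
        "n_drps": n_drp,
        "n_drpgs": int(drpg.nunique()),
        "n_aps": int(res.ap_table["is_ap"].sum()),
        "n_ap_genes": int(res.ap_table.loc[res.ap_table["is_ap"],
                                           "gene_id"].nunique()),
        "n_switch_genes": len(res.switch_genes),
    }
    if res.integration is not None:
        cls = res.integration.loc[res.integration["is_ap"], "corr_class"]
        n_linked_aps = int(len(cls))
        summary.update({
            "n_linked_aps": n_linked_aps,
            "n_mraps": len(res.mraps),
            "pct_ap_negative": (100.0 * (cls == "negative").mean()
                                if n_linked_aps else float("nan")),
            "pct_ap_positive": (100.0 * (cls == "positive").mean()
                                if n_linked_aps else float("nan")),
            "group_correlations": res.group_correlations,
        })
    if res.diagnostic is not None:
        summary["n_diagnostic_promoters"] = len(
            res.diagnostic.selected_promoters)
        summary["diagnostic_auc"] = float(res.auc)
    if res.survival is not None:
        tested = res.survival[res.survival["status"] == "tested"]
        summary["n_prognostic_mraps"] = int(tested["is_prognostic"].sum())
        summary["n_tested_mraps"] = int(len(tested))
        summary["pct_prognostic_mraps"] = (
            100.0 * tested["is_prognostic"].mean() if len(tested)
            else float("nan"))
    return summary


# ---------------------------------------------------------------------------
# file-based stages

def _load_catalog(outdir) -> PromoterAnnotation:
    return PromoterAnnotation.from_frame(
        pd.read_csv(Path(outdir) / "promoters.tsv", sep="\t"))


def _load_matrix(outdir, name) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / name, sep="\t", index_col=0)


def stage_promoters(gtf, outdir) -> PromoterAnnotation:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = flag_internal_promoters(build_promoters(parse_gene_models(gtf)))
    catalog.to_frame().to_csv(out / "promoters.tsv", sep="\t", index=False)
    catalog.to_bed().to_csv(out / "promoters.bed", sep="\t", index=False,
                            header=False)
    return catalog


def stage_activity(design_path, outdir) -> ActivityMatrix:
    out = Path(outdir)
    catalog = _load_catalog(out)
    design = _read_design(design_path)
    junctions = {row.sample_id: read_junction_table(row.sj_path)
                 for row in design.itertuples(index=False)}
    activity = promoter_activity(junctions, catalog, design)
    activity.raw_counts.to_csv(out / "raw_counts.tsv", sep="\t")
    activity.size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
    activity.absolute.to_csv(out / "absolute_activity.tsv", sep="\t")
    activity.relative.to_csv(out / "relative_activity.tsv", sep="\t")
    activity.gene_absolute.to_csv(out / "gene_absolute.tsv", sep="\t")
    activity.removal_log.to_csv(out / "removed_promoters.tsv", sep="\t",
                                index=False)
    return activity


def _rebuild_activity(outdir, catalog) -> ActivityMatrix:
    raw = _load_matrix(outdir, "raw_counts.tsv")
    sf = _load_matrix(outdir, "size_factors.tsv")["size_factor"]
    absolute = _load_matrix(outdir, "absolute_activity.tsv")
    relative = _load_matrix(outdir, "relative_activity.tsv")
    gene_abs = _load_matrix(outdir, "gene_absolute.tsv")
    return ActivityMatrix(raw_counts=raw, size_factors=sf, absolute=absolute,
                          relative=relative, gene_absolute=gene_abs,
                          gene_map=catalog.gene_map().reindex(raw.index))


def stage_diff(design_path, outdir, gene_counts_path: str = "",
               bh_correction: bool = False) -> None:
    out = Path(outdir)
    catalog = _load_catalog(out)
    design = _read_design(design_path)
    activity = _rebuild_activity(out, catalog)
    if gene_counts_path:
        gene_counts = pd.read_csv(gene_counts_path, sep="\t", index_col=0)
    else:
        gene_counts = activity.raw_counts.groupby(activity.gene_map).sum()
    gene_differential(gene_counts, design, bh_correction).to_csv(
        out / "gene_diff.tsv", sep="\t")
    promoter_differential(activity, design, bh_correction).to_csv(
        out / "promoter_diff.tsv", sep="\t")


def stage_aps(design_path, outdir, thresholds: APThresholds = APThresholds(),
              isoform_expression_path: str = "") -> None:
    out = Path(outdir)
    gene_diff = _load_matrix(out, "gene_diff.tsv")
    promoter_diff = _load_matrix(out, "promoter_diff.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap_table = identify_aps(gene_diff, promoter_diff, thresholds)
    if isoform_expression_path:
        catalog = _load_catalog(out)
        design = _read_design(design_path)
        iso = pd.read_csv(isoform_expression_path, sep="\t", index_col=0)
        iso_diff = gene_differential(iso, design)
        members = {p.promoter_id: p.member_transcripts for p in catalog}
        ap_table["isoform_class"] = classify_isoform_association(
            ap_table, members, iso_diff)
    ap_table.to_csv(out / "aps.tsv", sep="\t")
    pd.Series(find_switch_genes(ap_table), name="gene_id").to_csv(
        out / "switch_genes.tsv", sep="\t", index=False)


def stage_meth(design_path, beta_path, manifest_path, outdir) -> None:
    out = Path(outdir)
    catalog = _load_catalog(out)
    design = _read_design(design_path)
    meth = read_beta_matrix(beta_path, manifest_path)
    absolute = _load_matrix(out, "absolute_activity.tsv")
    promoter_diff = _load_matrix(out, "promoter_diff.tsv")
    ap_table = _load_matrix(out, "aps.tsv")
    drp_or_ap = promoter_diff.index[promoter_diff["is_drp"]
                                    | ap_table["is_ap"]]
    links = representative_cpgs(catalog, meth, absolute, design,
                                promoter_ids=list(drp_or_ap))
    links.to_csv(out / "links.tsv", sep="\t")


def stage_integrate(outdir, meth_delta: float = METH_DELTA) -> None:
    out = Path(outdir)
    promoter_diff = _load_matrix(out, "promoter_diff.tsv")
    ap_table = _load_matrix(out, "aps.tsv")
    links = _load_matrix(out, "links.tsv")
    table = integrate(promoter_diff, ap_table, links, meth_delta=meth_delta)
    table.to_csv(out / "integration.tsv", sep="\t")
    corr = {}
    for name, col in (("DRP", "is_drp"), ("AP", "is_ap"), ("mrAP", "is_mrap")):
        sub = table[table[col]]
        r, p = group_correlation_test(sub["delta_meth"], sub["norm_fc"],
                                      meth_delta=meth_delta)
        corr[name] = {"R": None if np.isnan(r) else r,
                      "p": None if np.isnan(p) else p, "n": int(len(sub))}
    (out / "group_correlations.json").write_text(
        json.dumps(corr, indent=2, sort_keys=True))


def stage_diagnose(design_path, outdir, folds: int = 10, seed: int = 0) -> None:
    out = Path(outdir)
    design = normalize_design(_read_design(design_path))
    integration = _load_matrix(out, "integration.tsv")
    absolute = _load_matrix(out, "absolute_activity.tsv")
    features = sorted(integration.index[integration["is_mrap"]])
    if not features:
        warnings.warn("no mrAPs: diagnostic stage skipped")
        return
    X = absolute.loc[features].T
    labels = design["condition"].reindex(X.index)
    model = fit_diagnostic(X, labels, folds=folds, seed=seed)
    (out / "diagnostic_model.json").write_text(
        json.dumps(model.to_dict(), indent=2, sort_keys=True))
    scores = score_samples(model, X)
    pd.DataFrame({"score": scores, "condition": labels}).to_csv(
        out / "diagnostic_scores.tsv", sep="\t")
    y = (labels == "tumor").to_numpy(dtype=int)
    order = np.argsort(-scores.to_numpy())
    tpr = np.concatenate([[0], np.cumsum(y[order]) / max(y.sum(), 1)])
    fpr = np.concatenate([[0], np.cumsum(1 - y[order]) / max((1 - y).sum(), 1)])
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / "roc_points.tsv",
                                                  sep="\t", index=False)


def stage_survive(cohort_beta_path, clinical_path, outdir,
                  minprop: float = MINPROP,
                  horizon: float = HORIZON_YEARS) -> None:
    out = Path(outdir)
    integration = _load_matrix(out, "integration.tsv")
    links = _load_matrix(out, "links.tsv")
    mraps = sorted(integration.index[integration["is_mrap"]])
    if not mraps:
        warnings.warn("no mrAPs: survival stage skipped")
        return
    cohort_beta = pd.read_csv(cohort_beta_path, sep="\t", index_col=0)
    clinical = read_clinical(clinical_path)
    flag_prognostic_mraps(links.loc[mraps], cohort_beta, clinical,
                          minprop=minprop, horizon=horizon).to_csv(
        out / "survival.tsv", sep="\t")


STAGES = ("promoters", "activity", "diff", "aps", "meth", "integrate",
          "diagnose", "survive")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages in dependency order and write ``summary.json``.

    The methylation/clinical stages are skipped with a warning when their
    input paths are not configured; earlier artifacts are still written.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_promoters(config.gtf, out)
    stage_activity(config.design, out)
    stage_diff(config.design, out, config.gene_counts, config.bh_correction)
    stage_aps(config.design, out, config.thresholds,
              config.isoform_expression)
    has_meth = bool(config.beta_matrix and config.manifest)
    if has_meth:
        stage_meth(config.design, config.beta_matrix, config.manifest, out)
        stage_integrate(out, config.meth_delta)
        stage_diagnose(config.design, out, config.folds, config.seed)
        if config.cohort_beta and config.clinical:
            stage_survive(config.cohort_beta, config.clinical, out,
                          config.minprop, config.horizon)
        else:
            warnings.warn("clinical inputs missing: survival stage skipped")
    else:
        warnings.warn("methylation inputs missing: "
                      "integration/clinical stages skipped")

    summary = _collect_summary(out)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary


def _collect_summary(outdir) -> dict:
    out = Path(outdir)
    promoter_diff = _load_matrix(out, "promoter_diff.tsv")
    gene_diff = _load_matrix(out, "gene_diff.tsv")
    ap_table = _load_matrix(out, "aps.tsv")
    switch = pd.read_csv(out / "switch_genes.tsv", sep="\t")
    summary = {
        "n_promoters": int(len(promoter_diff)),
        "n_genes": int(len(gene_diff)),
        "n_degs": int(gene_diff["is_deg"].sum()),
        "n_drps": int(promoter_diff["is_drp"].sum()),
        "n_drpgs": int(promoter_diff.loc[promoter_diff["is_drp"],
                                         "gene_id"].nunique()),
        "n_aps": int(ap_table["is_ap"].sum()),
        "n_switch_genes": int(len(switch)),
    }
    if (out / "integration.tsv").exists():
        integration = _load_matrix(out, "integration.tsv")
        summary["n_mraps"] = int(integration["is_mrap"].sum())
        summary["group_correlations"] = json.loads(
            (out / "group_correlations.json").read_text())
    if (out / "diagnostic_model.json").exists():
        model = json.loads((out / "diagnostic_model.json").read_text())
        summary["n_diagnostic_promoters"] = len(model["selected_promoters"])
    if (out / "survival.tsv").exists():
        surv = _load_matrix(out, "survival.tsv")
        tested = surv[surv["status"] == "tested"]
        summary["n_prognostic_mraps"] = int(tested["is_prognostic"].sum())
        summary["n_tested_mraps"] = int(len(tested))
    return summary
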