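"""Synthetic paired tumor/normal data with planted promoter-level truth.

The generator emulates the data-generating assumptions behind the analysis:
a toy multi-promoter genome, negative-binomial splice-junction counts for
paired tumor/normal samples, CpG betas around each TSS with an optional
planted negative coupling to promoter activity, and a survival cohort whose
hazard depends on the methylation group of planted prognostic CpGs.

Planted classes
---------------
* ``deg``    — every promoter of the gene scales by ``deg_fc`` in tumor.
* ``ap``     — one promoter's count mean drops by ``1/ap_fc`` in tumor, the
  released mass going to its sibling promoters so the gene total is constant
  (the defining structure of an alternative promoter).
* ``switch`` — a high-usage (1.5x baseline) and a low-usage (0.5x) promoter
  swap their means in tumor, planting one up- and one down-regulated AP in
  the same gene while the gene total stays constant.
* ``stable`` — no effect.

Because the promoter fold-change criterion is a ratio of mean log2
activities under a constant gene total, a strong up-shift is only possible
when a sibling promoter drops sharply; planted up-APs therefore live in
switch genes.

Truth tables are keyed by (gene_id, tss) so they can be joined to any
promoter catalog rebuilt from the emitted GTF
(:func:`match_truth_to_catalog`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "simulate_annotation",
    "simulate_junction_counts",
    "simulate_methylation",
    "simulate_survival",
    "simulate_dataset",
    "match_truth_to_catalog",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study where stated (19 tumor/normal pairs;
    4-fold planted expression changes; 1.2-fold-detectable promoter shifts
    driven by ``ap_fc``; a 3-fold methylation-group hazard ratio) and
    otherwise use values realistic for moderate-depth bulk RNA-seq and 450K
    arrays: a lognormal(ln 15, 0.4) per-promoter mean of unique junction
    reads, negative-binomial dispersion 0.05, promoters-per-gene
    probabilities (0.43, 0.37, 0.20) giving ~57% multi-promoter genes, and
    5 CpGs per promoter within +-1 kb of the TSS.
    """

    n_genes: int = 200
    promoters_per_gene_probs: tuple[float, ...] = (0.43, 0.37, 0.20)
    n_pairs: int = 19
    nb_dispersion: float = 0.05
    baseline_mean: float = 15.0
    baseline_log_sd: float = 0.4
    deg_fc: float = 4.0
    ap_fc: float = 2.0
    fraction_deg: float = 0.15
    fraction_ap: float = 0.15
    fraction_switch: float = 0.05
    fraction_mrap: float = 0.6
    fraction_prognostic: float = 0.5
    meth_coupling_slope: float = -1.5
    meth_noise_sd: float = 0.2
    cpgs_per_promoter: int = 5
    n_cohort: int = 200
    baseline_hazard: float = math.log(2) / 4.0   # median 4 years, per year
    hazard_ratio: float = 3.0
    censor_rate: float = 0.25
    pair_effect_sd: float = 0.25
    library_sd: float = 0.2
    seed: int = 0


@dataclass
class _Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]        # genomic, half-open, sorted
    sj_row: tuple                        # 1-based SJ.out.tab key fields


@dataclass
class _Promoter:
    key: str                             # gene.pK
    tss: int
    transcripts: list[_Transcript]
    mean_normal: float = 0.0
    mean_tumor: float = 0.0


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    promoters: list[_Promoter]
    gene_class: str = "stable"
    deg_direction: str = ""


@dataclass
class SimulatedDataset:
    design: SimulationDesign
    gtf_text: str
    genes: list[_Gene] = field(repr=False, default_factory=list)
    sample_design: pd.DataFrame = None
    sj_tables: dict[str, pd.DataFrame] = field(repr=False, default=None)
    counts: pd.DataFrame = field(repr=False, default=None)
    library_factors: pd.Series = None
    truth_genes: pd.DataFrame = None
    truth_promoters: pd.DataFrame = None
    truth_cpgs: pd.DataFrame = None
    beta: pd.DataFrame = field(repr=False, default=None)
    manifest: pd.DataFrame = field(repr=False, default=None)
    cohort_beta: pd.DataFrame = field(repr=False, default=None)
    clinical: pd.DataFrame = None

    def junction_tables(self) -> dict[str, pd.DataFrame]:
        """SJ tables rendered through the real SJ.out.tab parser."""
        import io

        from .activity import read_junction_table

        return {
            s: read_junction_table(io.StringIO(
                t.to_csv(sep="\t", header=False, index=False)))
            for s, t in self.sj_tables.items()
        }

    def write(self, outdir) -> Path:
        """Write GTF, per-sample SJ files, design, methylation, clinical
        tables, truth tables and a run config into ``outdir``."""
        out = Path(outdir)
        (out / "sj").mkdir(parents=True, exist_ok=True)
        (out / "annotation.gtf").write_text(self.gtf_text)
        paths = {}
        for sample, table in self.sj_tables.items():
            p = out / "sj" / f"{sample}.SJ.out.tab"
            table.to_csv(p, sep="\t", header=False, index=False)
            paths[sample] = str(p)
        design = self.sample_design.copy()
        design["sj_path"] = design["sample_id"].map(paths)
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        self.beta.to_csv(out / "beta.tsv", sep="\t")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.cohort_beta.to_csv(out / "cohort_beta.tsv", sep="\t")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        self.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.truth_promoters.to_csv(out / "truth_promoters.tsv", sep="\t",
                                    index=False)
        self.truth_cpgs.to_csv(out / "truth_cpgs.tsv", sep="\t", index=False)
        import yaml

        cfg = {
            "gtf": str(out / "annotation.gtf"),
            "design": str(out / "design.tsv"),
            "beta_matrix": str(out / "beta.tsv"),
            "manifest": str(out / "manifest.tsv"),
            "cohort_beta": str(out / "cohort_beta.tsv"),
            "clinical": str(out / "clinical.tsv"),
            "seed": int(self.design.seed),
        }
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        return out


# ---------------------------------------------------------------------------
# annotation

_GENE_SPAN = 50_000
_FIRST_EXON_LEN = 300
_TSS_SHIFT = 40          # TSS offset of the second transcript in a promoter
_PROMOTER_SPACING = 4_000
_EXON2_LEN = 250


def _make_transcript(gene: str, chrom: str, strand: str, offset: int,
                     k: int, j: int) -> tuple[int, _Transcript]:
    """Build transcript j of promoter k; returns (promoter tss, transcript)."""
    tid = f"{gene}.p{k + 1}.t{j + 1}"
    if strand == "+":
        tss_k = offset + 1_000 + k * _PROMOTER_SPACING
        fs = tss_k + _TSS_SHIFT * j
        fe = fs + _FIRST_EXON_LEN
        s2 = offset + 25_000 + k * 700 + j * 350
        exons = [(fs, fe), (s2, s2 + _EXON2_LEN)]
        sj = (chrom, fe + 1, s2, 1)        # 1-based inclusive intron
    else:
        tss_k = offset + 45_000 - k * _PROMOTER_SPACING
        fe = tss_k + 1 - _TSS_SHIFT * j
        fs = fe - _FIRST_EXON_LEN
        s2 = offset + 2_000 + k * 700 + j * 350
        exons = [(s2, s2 + _EXON2_LEN), (fs, fe)]
        sj = (chrom, s2 + _EXON2_LEN + 1, fs, 2)
    return tss_k, _Transcript(transcript_id=tid, exons=exons, sj_row=sj)


def simulate_annotation(design: SimulationDesign,
                        rng: np.random.Generator | None = None
                        ) -> tuple[str, list[_Gene]]:
    """Toy genome: one chromosome per 100 genes, 1-3 promoters per gene,
    1-2 multi-exon transcripts per promoter.  Deterministic under seed."""
    if rng is None:
        rng = np.random.default_rng([design.seed, 0])
    genes: list[_Gene] = []
    probs = np.asarray(design.promoters_per_gene_probs, dtype=float)
    probs = probs / probs.sum()
    for i in range(design.n_genes):
        gene_id = f"gene{i + 1:04d}"
        chrom = f"chrS{i // 100 + 1}"
        offset = (i % 100) * _GENE_SPAN
        strand = "+" if rng.random() < 0.5 else "-"
        n_prom = int(rng.choice(len(probs), p=probs)) + 1
        promoters = []
        for k in range(n_prom):
            n_tx = 1 if rng.random() < 0.6 else 2
            txs = []
            tss = None
            for j in range(n_tx):
                t, tx = _make_transcript(gene_id, chrom, strand, offset, k, j)
                if j == 0:
                    tss = t
                txs.append(tx)
            promoters.append(_Promoter(key=f"{gene_id}.p{k + 1}", tss=tss,
                                       transcripts=txs))
        genes.append(_Gene(gene_id=gene_id, chrom=chrom, strand=strand,
                           promoters=promoters))

    lines = []
    for g in genes:
        for p in g.promoters:
            for tx in p.transcripts:
                attrs = (f'gene_id "{g.gene_id}"; '
                         f'transcript_id "{tx.transcript_id}";')
                start = min(s for s, _ in tx.exons) + 1
                end = max(e for _, e in tx.exons)
                lines.append("\t".join(map(str, (
                    g.chrom, "sim", "transcript", start, end, ".",
                    g.strand, ".", attrs))))
                for s, e in tx.exons:
                    lines.append("\t".join(map(str, (
                        g.chrom, "sim", "exon", s + 1, e, ".",
                        g.strand, ".", attrs))))
    return "\n".join(lines) + "\n", genes


# ---------------------------------------------------------------------------
# classes and counts

def _assign_classes(design: SimulationDesign, genes: list[_Gene],
                    rng: np.random.Generator) -> None:
    """Assign gene classes and per-promoter normal/tumor count means in place."""
    n = design.n_genes
    multi = [g for g in genes if len(g.promoters) >= 2]
    order = rng.permutation(len(multi))
    n_switch = round(design.fraction_switch * n)
    n_ap = round(design.fraction_ap * n)
    switch_genes = [multi[i] for i in order[:n_switch]]
    ap_genes = [multi[i] for i in order[n_switch:n_switch + n_ap]]
    taken = {g.gene_id for g in switch_genes + ap_genes}
    rest = [g for g in genes if g.gene_id not in taken]
    order2 = rng.permutation(len(rest))
    deg_genes = [rest[i] for i in order2[:round(design.fraction_deg * n)]]

    for g in switch_genes:
        g.gene_class = "switch"
    for g in ap_genes:
        g.gene_class = "ap"
    for g in deg_genes:
        g.gene_class = "deg"

    for g in genes:
        mus = design.baseline_mean * np.exp(
            rng.normal(0.0, design.baseline_log_sd, size=len(g.promoters)))
        for p, mu in zip(g.promoters, mus):
            p.mean_normal = float(mu)
            p.mean_tumor = float(mu)
        if g.gene_class == "deg":
            g.deg_direction = "up" if rng.random() < 0.5 else "down"
            f = design.deg_fc if g.deg_direction == "up" else 1.0 / design.deg_fc
            for p in g.promoters:
                p.mean_tumor = p.mean_normal * f
        elif g.gene_class == "ap":
            d = int(rng.integers(len(g.promoters)))
            released = g.promoters[d].mean_normal * (1 - 1 / design.ap_fc)
            g.promoters[d].mean_tumor = (g.promoters[d].mean_normal
                                         / design.ap_fc)
            sib_total = sum(p.mean_normal for i, p in enumerate(g.promoters)
                            if i != d)
            for i, p in enumerate(g.promoters):
                if i != d:
                    p.mean_tumor = p.mean_normal * (1 + released / sib_total)
        elif g.gene_class == "switch":
            a, b = rng.choice(len(g.promoters), size=2, replace=False)
            c = design.baseline_mean * math.exp(
                rng.normal(0.0, design.baseline_log_sd))
            g.promoters[a].mean_normal = 1.5 * c
            g.promoters[b].mean_normal = 0.5 * c
            g.promoters[a].mean_tumor = 0.5 * c
            g.promoters[b].mean_tumor = 1.5 * c


def _truth_tables(design: SimulationDesign, genes: list[_Gene]
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    gene_rows, prom_rows = [], []
    log_thr = math.log2(1.2)
    for g in genes:
        gene_rows.append({"gene_id": g.gene_id, "gene_class": g.gene_class,
                          "n_promoters": len(g.promoters),
                          "strand": g.strand})
        for p in g.promoters:
            lfc = (math.log2(p.mean_tumor + 1) - math.log2(p.mean_normal + 1))
            is_ap = (g.gene_class in ("ap", "switch")
                     and p.mean_tumor != p.mean_normal
                     and abs(math.log2((math.log2(p.mean_tumor + 1))
                                       / (math.log2(p.mean_normal + 1))))
                     > log_thr)
            direction = ("none" if p.mean_tumor == p.mean_normal else
                         ("up" if p.mean_tumor > p.mean_normal else "down"))
            is_drp = is_ap or g.gene_class == "deg"
            prom_rows.append({
                "promoter_key": p.key, "gene_id": g.gene_id,
                "chrom": g.chrom, "strand": g.strand, "tss": p.tss,
                "mean_normal": p.mean_normal, "mean_tumor": p.mean_tumor,
                "true_log2_fc_counts": lfc,
                "is_ap": bool(is_ap), "is_drp": bool(is_drp),
                "direction": direction if is_drp else "none",
                "is_mrap": False,  # filled once CpG coupling is drawn
            })
    return pd.DataFrame(gene_rows), pd.DataFrame(prom_rows)


def simulate_junction_counts(design: SimulationDesign, genes: list[_Gene],
                             rng: np.random.Generator
                             ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame,
                                        pd.DataFrame, pd.Series]:
    """Per-sample SJ tables plus the promoter count matrix.

    Counts are negative binomial with mean
    mu(promoter, condition) * pair_effect(gene, pair) * library(sample)
    and dispersion ``nb_dispersion`` (variance mu + dispersion * mu^2).
    Promoter counts are split over member transcripts' first junctions, so
    each SJ file column-7 total equals its count-matrix column sum.
    """
    samples, conditions, pairs = [], [], []
    for p in range(1, design.n_pairs + 1):
        for cond, tag in (("tumor", "T"), ("normal", "N")):
            samples.append(f"S{p:02d}{tag}")
            conditions.append(cond)
            pairs.append(f"P{p:02d}")
    sample_design = pd.DataFrame({"sample_id": samples,
                                  "condition": conditions, "pair_id": pairs})

    lib = pd.Series(np.exp(rng.normal(0.0, design.library_sd, len(samples))),
                    index=samples, name="library_factor")
    pair_ids = sorted(set(pairs))
    pair_eff = {(g.gene_id, pid): math.exp(rng.normal(0.0, design.pair_effect_sd))
                for g in genes for pid in pair_ids}

    prom_keys = [p.key for g in genes for p in g.promoters]
    counts = np.zeros((len(prom_keys), len(samples)), dtype=int)
    tx_counts: dict[tuple[str, str], int] = {}

    row = 0
    for g in genes:
        for p in g.promoters:
            for si, s in enumerate(samples):
                mu = (p.mean_tumor if conditions[si] == "tumor"
                      else p.mean_normal)
                mu *= pair_eff[(g.gene_id, pairs[si])] * lib[s]
                if design.nb_dispersion <= 0:
                    c = int(rng.poisson(mu))
                else:
                    size = 1.0 / design.nb_dispersion
                    c = int(rng.negative_binomial(size, size / (size + mu)))
                counts[row, si] = c
                ntx = len(p.transcripts)
                if ntx == 1:
                    split = [c]
                else:
                    split = rng.multinomial(c, [0.65, 0.35])
                for tx, ct in zip(p.transcripts, split):
                    tx_counts[(tx.transcript_id, s)] = int(ct)
            row += 1

    sj_tables = {}
    for s in samples:
        rows = []
        for g in genes:
            for p in g.promoters:
                for tx in p.transcripts:
                    c = tx_counts[(tx.transcript_id, s)]
                    if c == 0:
                        continue
                    chrom, istart, iend, code = tx.sj_row
                    rows.append((chrom, istart, iend, code, 1, 1, c, 0, 50))
        df = pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end",
                                         "strand_code", "motif", "annotated",
                                         "unique_reads", "multi_reads",
                                         "max_overhang"])
        sj_tables[s] = df.sort_values(
            ["chrom", "intron_start", "intron_end"]).reset_index(drop=True)

    count_df = pd.DataFrame(counts, index=pd.Index(prom_keys,
                                                   name="promoter_key"),
                            columns=samples)
    return sj_tables, count_df, sample_design, lib


# ---------------------------------------------------------------------------
# methylation and survival

def simulate_methylation(design: SimulationDesign, genes: list[_Gene],
                         truth_promoters: pd.DataFrame,
                         counts: pd.DataFrame, lib: pd.Series,
                         rng_truth: np.random.Generator,
                         rng_data: np.random.Generator
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CpG betas around each TSS; coupled CpGs anti-track promoter activity.

    For each AP promoter selected as methylation-regulated (probability
    ``fraction_mrap``), one CpG's beta is inverse-logit(a0 + slope * z +
    noise) where z is the promoter's standardized log2 activity across
    samples; other CpGs are independent Beta(2, 2).  Betas are clipped to
    [0.01, 0.99].  Returns (beta matrix, manifest, truth_cpgs) and fills the
    ``is_mrap`` truth column.
    """
    samples = list(counts.columns)
    activity = np.log2(counts.div(lib, axis=1) + 1.0)
    truth = truth_promoters.set_index("promoter_key")

    probe_rows, beta_rows, cpg_rows = [], [], []
    idx = 0
    for g in genes:
        for p in g.promoters:
            coupled_here = (bool(truth.loc[p.key, "is_ap"])
                            and rng_truth.random() < design.fraction_mrap)
            n_cpg = design.cpgs_per_promoter
            positions = set()
            while len(positions) < n_cpg:
                positions.add(int(rng_truth.integers(p.tss - 1000,
                                                     p.tss + 1001)))
            a0 = float(rng_truth.normal(0.0, 0.7))
            if coupled_here:
                truth.loc[p.key, "is_mrap"] = True
            for ci, pos in enumerate(sorted(positions)):
                idx += 1
                probe_id = f"cg{idx:08d}"
                is_coupled = coupled_here and ci == 0
                if is_coupled:
                    a = activity.loc[p.key].to_numpy()
                    sd = a.std()
                    z = (a - a.mean()) / (sd if sd > 0 else 1.0)
                    logit = (a0 + design.meth_coupling_slope * z
                             + rng_data.normal(0.0, design.meth_noise_sd,
                                               len(samples)))
                    beta = np.clip(expit(logit), 0.01, 0.99)
                    r = float(np.corrcoef(beta, a)[0, 1]) if sd > 0 else 0.0
                else:
                    beta = np.clip(rng_data.beta(2.0, 2.0, len(samples)),
                                   0.01, 0.99)
                    r = 0.0
                probe_rows.append({"probe_id": probe_id, "chrom": g.chrom,
                                   "pos": pos + 1})  # manifest is 1-based
                beta_rows.append(beta)
                cpg_rows.append({"probe_id": probe_id, "promoter_key": p.key,
                                 "gene_id": g.gene_id,
                                 "is_coupled": bool(is_coupled),
                                 "true_r": r, "is_prognostic": False})

    manifest = pd.DataFrame(probe_rows)
    beta = pd.DataFrame(np.vstack(beta_rows), columns=samples,
                        index=pd.Index(manifest["probe_id"], name="probe_id"))
    truth_cpgs = pd.DataFrame(cpg_rows)

    coupled_idx = truth_cpgs.index[truth_cpgs["is_coupled"]]
    for i in coupled_idx:
        if rng_truth.random() < design.fraction_prognostic:
            truth_cpgs.loc[i, "is_prognostic"] = True

    truth_promoters["is_mrap"] = truth.reset_index()["is_mrap"].to_numpy()
    return beta, manifest, truth_cpgs


def simulate_survival(design: SimulationDesign, truth_cpgs: pd.DataFrame,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival cohort whose hazard tracks prognostic-CpG methylation.

    A latent binary risk group u drives both the prognostic CpG betas
    (Beta(8,2) for u=1, Beta(2,8) for u=0, so beta > median recovers u) and
    the hazard baseline_hazard * hazard_ratio^u.  Non-prognostic CpGs are
    Beta(2,2).  With probability ``censor_rate`` a subject is censored at a
    uniform fraction of its event time.  Returns (clinical table with
    sample_id / time in years / event, cohort beta matrix).
    """
    n = design.n_cohort
    subjects = [f"C{i + 1:03d}" for i in range(n)]
    u = rng.integers(0, 2, size=n)

    rows = []
    for _, cpg in truth_cpgs.iterrows():
        if cpg["is_prognostic"]:
            b = np.where(u == 1, rng.beta(8.0, 2.0, n), rng.beta(2.0, 8.0, n))
        else:
            b = rng.beta(2.0, 2.0, n)
        rows.append(np.clip(b, 0.01, 0.99))
    cohort_beta = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n)),
        index=pd.Index(truth_cpgs["probe_id"], name="probe_id"),
        columns=subjects)

    rate = design.baseline_hazard * design.hazard_ratio ** u
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < design.censor_rate
    t_obs = np.where(censored, rng.uniform(0.0, 1.0, n) * t_event, t_event)
    clinical = pd.DataFrame({
        "sample_id": subjects,
        "time": np.round(t_obs, 4),
        "event": (~censored).astype(int),
        "risk_group": u,
    })
    return clinical, cohort_beta


def simulate_dataset(design: SimulationDesign,
                     data_seed: int | None = None) -> SimulatedDataset:
    """Generate the full synthetic study.

    ``design.seed`` fixes the genome layout, class assignment and planted
    effect sizes; ``data_seed`` (defaulting to the same seed) fixes the
    stochastic realization — counts, betas, survival — so replicate cohorts
    with identical planted truth can be drawn by varying ``data_seed`` only.
    """
    if data_seed is None:
        data_seed = design.seed
    rng_truth = np.random.default_rng([int(design.seed), 0])
    rng_data = np.random.default_rng([int(data_seed), 1])

    gtf_text, genes = simulate_annotation(design, rng_truth)
    _assign_classes(design, genes, rng_truth)
    truth_genes, truth_promoters = _truth_tables(design, genes)
    sj_tables, counts, sample_design, lib = simulate_junction_counts(
        design, genes, rng_data)
    beta, manifest, truth_cpgs = simulate_methylation(
        design, genes, truth_promoters, counts, lib, rng_truth, rng_data)
    clinical, cohort_beta = simulate_survival(design, truth_cpgs, rng_data)
    return SimulatedDataset(
        design=design, gtf_text=gtf_text, genes=genes,
        sample_design=sample_design, sj_tables=sj_tables, counts=counts,
        library_factors=lib, truth_genes=truth_genes,
        truth_promoters=truth_promoters, truth_cpgs=truth_cpgs,
        beta=beta, manifest=manifest, cohort_beta=cohort_beta,
        clinical=clinical)


def simulate_diagnostic_features(n_samples: int = 40, n_features: int = 50,
                                 n_planted: int = 2, shift: float = 3.0,
                                 seed: int = 1
                                 ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Separable diagnostic fixture: tumor samples shifted on planted features.

    Features are standard normal; in tumor samples the planted features are
    shifted by ``shift`` (3 standard deviations by default, giving nearly
    separable classes).  Returns (samples x features activity, labels,
    planted feature names).
    """
    rng = np.random.default_rng(seed)
    n_t = n_samples // 2
    X = rng.normal(size=(n_samples, n_features))
    planted = sorted(rng.choice(n_features, size=n_planted, replace=False))
    X[:n_t, planted] += shift
    cols = [f"prmtr.{j + 1}" for j in range(n_features)]
    idx = [f"S{i + 1:02d}" for i in range(n_samples)]
    labels = pd.Series(["tumor"] * n_t + ["normal"] * (n_samples - n_t),
                       index=idx, name="condition")
    return (pd.DataFrame(X, index=idx, columns=cols), labels,
            [cols[j] for j in planted])


def match_truth_to_catalog(truth_promoters: pd.DataFrame, catalog
                           ) -> pd.Series:
    """Map truth promoter keys to catalog promoter ids via (gene_id, tss)."""
    lookup = {(p.gene_id, p.tss): p.promoter_id for p in catalog}
    keys = list(zip(truth_promoters["gene_id"], truth_promoters["tss"]))
    return pd.Series([lookup.get(k) for k in keys],
                     index=truth_promoters["promoter_key"],
                     name="promoter_id")
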