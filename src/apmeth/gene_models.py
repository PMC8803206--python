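"""Gene models and the promoter catalog.

Transcripts are read from a Gencode-style GTF and grouped into promoters by
strand-aware single-linkage clustering of their first exons: two transcripts
of the same gene belong to the same promoter whenever their first exons
overlap.  Each promoter carries the set of splice-donor coordinates at the 3'
ends of its member first exons; downstream, promoter activity is the number
of unique junction reads leaving those donor sites.

Coordinates are 0-based half-open internally.  GTF input (1-based inclusive)
and BED output (0-based half-open) are converted at the boundary.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "Promoter",
    "PromoterAnnotation",
    "parse_gene_models",
    "build_promoters",
    "flag_internal_promoters",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of exons in transcription direction.

    ``exons`` are 0-based half-open genomic intervals sorted 5'->3' in
    transcription direction (descending genomic coordinate on the minus
    strand).  ``tss`` is the first transcribed base: the genomic start of
    ``exons[0]`` on '+', its genomic end minus one on '-'.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        s, e = self.exons[0]
        return s if self.strand == "+" else e - 1

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0]

    @property
    def donor_site(self) -> int | None:
        """Splice-donor coordinate of the first intron, or None if single-exon.

        On '+' this is the half-open end of the first exon (equal to the
        0-based intron start); on '-' it is the genomic start of the first
        exon (equal to the half-open intron end).
        """
        if len(self.exons) == 1:
            return None
        s, e = self.exons[0]
        return e if self.strand == "+" else s

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1


@dataclass(frozen=True)
class Promoter:
    promoter_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    member_transcripts: tuple[str, ...]
    donor_sites: frozenset[int]
    cluster_start: int
    cluster_end: int
    is_internal: bool = False
    is_single_exon_only: bool = False


class PromoterAnnotation:
    """Promoter catalog plus the transcripts it was built from."""

    def __init__(self, promoters: Sequence[Promoter],
                 transcripts: Sequence[TranscriptModel] = ()):
        self.promoters: list[Promoter] = list(promoters)
        self.transcripts: list[TranscriptModel] = list(transcripts)
        ids = [p.promoter_id for p in self.promoters]
        if len(set(ids)) != len(ids):
            raise ValueError("promoter ids are not unique")
        self._by_id = {p.promoter_id: p for p in self.promoters}

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self) -> Iterator[Promoter]:
        return iter(self.promoters)

    def __getitem__(self, promoter_id: str) -> Promoter:
        return self._by_id[promoter_id]

    def __contains__(self, promoter_id: str) -> bool:
        return promoter_id in self._by_id

    @property
    def promoter_ids(self) -> list[str]:
        return [p.promoter_id for p in self.promoters]

    def gene_map(self) -> pd.Series:
        """promoter_id -> gene_id."""
        return pd.Series({p.promoter_id: p.gene_id for p in self.promoters},
                         name="gene_id")

    def donor_index(self) -> pd.DataFrame:
        """Long table (chrom, strand, donor, promoter_id, gene_id).

        Within one gene a donor coordinate maps to a single promoter: first
        exons sharing a 3' (or 5') boundary necessarily overlap and are
        clustered together.  Asserted here because promoter counting relies
        on it to avoid double counting.
        """
        rows = [
            (p.chrom, p.strand, d, p.promoter_id, p.gene_id)
            for p in self.promoters
            for d in sorted(p.donor_sites)
        ]
        df = pd.DataFrame(rows, columns=["chrom", "strand", "donor",
                                         "promoter_id", "gene_id"])
        dup = df.duplicated(subset=["chrom", "strand", "donor", "gene_id"])
        assert not dup.any(), "donor site shared by two promoters of one gene"
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "promoter_id": [p.promoter_id for p in self.promoters],
                "gene_id": [p.gene_id for p in self.promoters],
                "chrom": [p.chrom for p in self.promoters],
                "strand": [p.strand for p in self.promoters],
                "tss": [p.tss for p in self.promoters],
                "cluster_start": [p.cluster_start for p in self.promoters],
                "cluster_end": [p.cluster_end for p in self.promoters],
                "member_transcripts": [",".join(p.member_transcripts)
                                       for p in self.promoters],
                "donor_sites": [",".join(map(str, sorted(p.donor_sites)))
                                for p in self.promoters],
                "is_internal": [p.is_internal for p in self.promoters],
                "is_single_exon_only": [p.is_single_exon_only
                                        for p in self.promoters],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PromoterAnnotation":
        promoters = []
        for row in df.itertuples(index=False):
            donors = frozenset(
                int(x) for x in str(row.donor_sites).split(",") if x not in ("", "nan")
            )
            promoters.append(Promoter(
                promoter_id=row.promoter_id,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                member_transcripts=tuple(str(row.member_transcripts).split(",")),
                donor_sites=donors,
                cluster_start=int(row.cluster_start),
                cluster_end=int(row.cluster_end),
                is_internal=bool(row.is_internal),
                is_single_exon_only=bool(row.is_single_exon_only),
            ))
        return cls(promoters)

    def to_bed(self) -> pd.DataFrame:
        """BED6+ rows over the first-exon cluster; score = member count."""
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.promoters],
                "start": [p.cluster_start for p in self.promoters],
                "end": [p.cluster_end for p in self.promoters],
                "name": [p.promoter_id for p in self.promoters],
                "score": [len(p.member_transcripts) for p in self.promoters],
                "strand": [p.strand for p in self.promoters],
                "gene_id": [p.gene_id for p in self.promoters],
                "is_internal": [int(p.is_internal) for p in self.promoters],
            }
        )


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        text = str(source)
        if isinstance(source, str) and ("\n" in text or "\t" in text):
            yield from io.StringIO(text)
            return
        with open(source) as fh:
            yield from fh
        return
    yield from source


def parse_gene_models(source) -> list[TranscriptModel]:
    """Parse exon features of a Gencode-style GTF into transcript models.

    ``source`` may be a file path, GTF text, or an iterable of lines.  GTF
    coordinates (1-based inclusive) become 0-based half-open; exons are
    returned in transcription order.  A transcript declared by a
    ``transcript`` feature but lacking exon records is skipped with a warning.
    """
    exons: dict[str, dict] = {}
    declared: set[str] = set()
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"GTF line {lineno}: expected 9 tab-separated fields")
        chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
        if feature not in ("exon", "transcript"):
            continue
        attr = dict(_ATTR_RE.findall(attrs))
        if "gene_id" not in attr or "transcript_id" not in attr:
            raise ValueError(
                f"GTF line {lineno}: missing mandatory gene_id/transcript_id attribute"
            )
        tid = attr["transcript_id"]
        if feature == "transcript":
            declared.add(tid)
            continue
        try:
            s, e = int(start) - 1, int(end)
        except ValueError:
            raise ValueError(f"GTF line {lineno}: non-numeric coordinates") from None
        if strand not in "+-":
            raise ValueError(f"GTF line {lineno}: strand must be + or -")
        rec = exons.setdefault(
            tid, {"gene_id": attr["gene_id"], "chrom": chrom,
                  "strand": strand, "exons": []}
        )
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise ValueError(
                f"GTF line {lineno}: transcript {tid} spans chromosomes/strands"
            )
        rec["exons"].append((s, e))

    missing = declared - set(exons)
    if missing:
        warnings.warn(
            f"{len(missing)} transcript(s) without exon records skipped: "
            + ", ".join(sorted(missing)[:5])
        )

    out = []
    for tid, rec in exons.items():
        ordered = sorted(rec["exons"], reverse=(rec["strand"] == "-"))
        out.append(TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(ordered),
        ))
    return out


def _cluster_intervals(items: list[tuple[tuple[int, int], TranscriptModel]]
                       ) -> list[list[TranscriptModel]]:
    """Single-linkage clustering of half-open intervals by overlap."""
    items = sorted(items, key=lambda it: (it[0], it[1].transcript_id))
    clusters: list[list[TranscriptModel]] = []
    cur: list[TranscriptModel] = []
    cur_end = None
    for (s, e), tx in items:
        if cur and s < cur_end:
            cur.append(tx)
            cur_end = max(cur_end, e)
        else:
            if cur:
                clusters.append(cur)
            cur, cur_end = [tx], e
    if cur:
        clusters.append(cur)
    return clusters


def build_promoters(transcripts: Iterable[TranscriptModel]) -> PromoterAnnotation:
    """Cluster transcripts into promoters by first-exon overlap.

    Promoter ids are assigned deterministically (sorted by chrom, tss,
    gene_id) as ``prmtr.1``, ``prmtr.2``, ...  Input order is irrelevant.
    """
    transcripts = list(transcripts)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    raw: list[Promoter] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            warnings.warn(f"gene {gene_id} has transcripts on both strands; "
                          "clustering per strand")
        for strand in sorted(strands):
            sub = [t for t in txs if t.strand == strand]
            for cluster in _cluster_intervals([(t.first_exon, t) for t in sub]):
                tss = (min(t.tss for t in cluster) if strand == "+"
                       else max(t.tss for t in cluster))
                donors = frozenset(t.donor_site for t in cluster
                                   if t.donor_site is not None)
                raw.append(Promoter(
                    promoter_id="",
                    gene_id=gene_id,
                    chrom=cluster[0].chrom,
                    strand=strand,
                    tss=tss,
                    member_transcripts=tuple(sorted(t.transcript_id
                                                    for t in cluster)),
                    donor_sites=donors,
                    cluster_start=min(t.first_exon[0] for t in cluster),
                    cluster_end=max(t.first_exon[1] for t in cluster),
                    is_single_exon_only=all(t.is_single_exon for t in cluster),
                ))

    raw.sort(key=lambda p: (p.chrom, p.tss, p.gene_id))
    promoters = [replace(p, promoter_id=f"prmtr.{i}")
                 for i, p in enumerate(raw, start=1)]
    return PromoterAnnotation(promoters, transcripts)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def flag_internal_promoters(catalog: PromoterAnnotation) -> PromoterAnnotation:
    """Flag promoters whose first-exon cluster lies inside a sibling's gene body.

    A promoter is internal when its first-exon cluster overlaps any non-first
    exon of another transcript of the same gene.  Junction counts at such
    promoters can pick up reads from the overlapping transcript; the flag is
    informational only and does not change counting.
    """
    body_exons: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for tx in catalog.transcripts:
        for exon in tx.exons[1:]:
            body_exons.setdefault(tx.gene_id, []).append((tx.transcript_id, exon))

    flagged = []
    for p in catalog.promoters:
        cluster = (p.cluster_start, p.cluster_end)
        members = set(p.member_transcripts)
        internal = any(
            tid not in members and _overlaps(cluster, exon)
            for tid, exon in body_exons.get(p.gene_id, [])
        )
        flagged.append(replace(p, is_internal=internal))
    return PromoterAnnotation(flagged, catalog.transcripts)
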