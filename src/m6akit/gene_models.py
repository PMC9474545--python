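"""Collapsed gene models from GTF/GFF3 annotation.

Transcript isoforms of a gene are collapsed into a single exon-union model
whose exonic bases are partitioned into 5'UTR, CDS and 3'UTR, following the
convention used in MeRIP-seq metagene analyses: the CDS region of the
collapsed model spans all exonic bases between the outermost CDS boundaries
over all transcripts, the 5'UTR is every exonic base 5' of that span in
transcript orientation, and the 3'UTR every exonic base 3' of it.

All internal coordinates are 0-based half-open; GTF/GFF3 (1-based inclusive)
is converted on read.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gffutils
import numpy as np

Interval = tuple[int, int]

REGIONS = ("utr5", "cds", "utr3")

FILTER_REASONS = ("missing_utr", "utr5_short", "utr3_short", "cds_short")

#: feature types accepted as transcripts in GFF3 input
TRANSCRIPT_TYPES = frozenset(
    {"mRNA", "transcript", "ncRNA", "lnc_RNA", "tRNA", "rRNA",
     "snoRNA", "snRNA", "pre_miRNA", "miRNA"}
)


class AnnotationError(ValueError):
    """Malformed annotation input (missing linkage attributes, orphan features)."""


class ValidationError(ValueError):
    """Structurally valid input violating a model invariant (mixed strands, ...)."""


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open, on one chromosome)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two disjoint-sorted interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intervals_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[Interval]          # sorted, disjoint, genomic
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        self.cds = merge_intervals(self.cds)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


@dataclass
class GenomeAnnotation:
    """Genes with their transcript exon/CDS structure, 0-based half-open."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            o = other.genes[gid]
            if (g.chrom, g.strand) != (o.chrom, o.strand):
                return False
            if set(g.transcripts) != set(o.transcripts):
                return False
            for tid, t in g.transcripts.items():
                ot = o.transcripts[tid]
                if t.exons != ot.exons or t.cds != ot.cds:
                    return False
        return True


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exon_segments: list[Interval]
    region_segments: dict[str, list[Interval]]
    coding: bool = True

    @property
    def region_lengths(self) -> dict[str, int]:
        return {r: intervals_length(self.region_segments[r]) for r in REGIONS}

    @property
    def exonic_length(self) -> int:
        return intervals_length(self.exon_segments)

    @property
    def span(self) -> Interval:
        return self.exon_segments[0][0], self.exon_segments[-1][1]


@dataclass
class ModelFilterReport:
    kept: list[str]
    excluded: list[tuple[str, str]]   # (gene_id, reason)


class PositionLabel(NamedTuple):
    region: str          # utr5 | cds | utr3 | exonic | intronic | intergenic
    offset: int | None   # spliced offset from the region's 5' end, transcript orientation


# ---------------------------------------------------------------------------
# spliced coordinate map
# ---------------------------------------------------------------------------

class SplicedMap:
    """Maps genomic coordinates to spliced (exon-concatenated) coordinates.

    "Forward-spliced" coordinates count exonic bases in genomic order;
    transcript coordinates mirror them on the minus strand. The exonic image
    of any genomic interval is contiguous in spliced space (introns vanish),
    which makes interval mapping a pair of rank queries.
    """

    def __init__(self, segments: Sequence[Interval], strand: str):
        self.segments = list(segments)
        self.strand = strand
        self._starts = np.asarray([s for s, _ in segments], dtype=np.int64)
        self._ends = np.asarray([e for _, e in segments], dtype=np.int64)
        widths = self._ends - self._starts
        self._cum = np.concatenate([[0], np.cumsum(widths)])
        self.length = int(self._cum[-1])

    def rank(self, pos) -> np.ndarray:
        """Number of exonic bases with genomic coordinate < pos (vectorized)."""
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(self._starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.segments) - 1)
        off = np.clip(pos - self._starts[idx_c], 0, self._ends[idx_c] - self._starts[idx_c])
        return np.where(idx < 0, 0, self._cum[idx_c] + off)

    def genomic_to_spliced(self, start: int, end: int) -> Interval | None:
        """Transcript-oriented spliced image of genomic [start, end); None if intronic."""
        a, b = int(self.rank(start)), int(self.rank(end))
        if b <= a:
            return None
        if self.strand == "-":
            a, b = self.length - b, self.length - a
        return a, b

    def spliced_to_genomic(self, start: int, end: int) -> list[Interval]:
        """Genomic segments covered by transcript-oriented spliced [start, end)."""
        if self.strand == "-":
            start, end = self.length - end, self.length - start
        out: list[Interval] = []
        for (gs, ge), c0, c1 in zip(self.segments, self._cum[:-1], self._cum[1:]):
            s = max(start, int(c0))
            e = min(end, int(c1))
            if e > s:
                out.append((gs + s - int(c0), gs + e - int(c0)))
        return out


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _to_internal(feature) -> Interval:
    # gffutils keeps 1-based inclusive coordinates
    return feature.start - 1, feature.end


def parse_annotation(path: str | os.PathLike, dialect: str = "gtf") -> GenomeAnnotation:
    """Parse a GTF or GFF3 file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path : file path
    dialect : ``"gtf"`` (gene_id/transcript_id attributes) or ``"gff3"``
        (ID/Parent linkage).

    Raises
    ------
    AnnotationError
        if an exon/CDS feature lacks its linkage attribute or names an
        unknown transcript, with the offending feature in the message.
    ValidationError
        if an exon lies outside its declared transcript span.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    # gene/transcript linkage is taken from attributes directly, so gffutils
    # feature inference is unnecessary (and slow) for both dialects
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )

    ann = GenomeAnnotation()
    tid_to_gid: dict[str, str] = {}
    declared_spans: dict[str, Interval] = {}

    if dialect == "gtf":
        for tf in db.features_of_type(("transcript", "mRNA")):
            try:
                gid = tf.attributes["gene_id"][0]
                tid = tf.attributes["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationError(
                    f"transcript feature at {tf.seqid}:{tf.start}-{tf.end} "
                    f"lacks attribute {exc}") from exc
            _register(ann, tid_to_gid, gid, tid, tf)
            declared_spans[tid] = _to_internal(tf)
        for kind in ("exon", "CDS"):
            for f in db.features_of_type(kind):
                try:
                    tid = f.attributes["transcript_id"][0]
                    gid = f.attributes["gene_id"][0]
                except KeyError as exc:
                    raise AnnotationError(
                        f"{kind} feature at {f.seqid}:{f.start}-{f.end} "
                        f"lacks attribute {exc}") from exc
                if tid not in tid_to_gid:
                    _register(ann, tid_to_gid, gid, tid, f)
                _add_piece(ann, tid_to_gid, tid, kind, f, declared_spans)
    else:
        gene_ids = set()
        for gf in db.features_of_type("gene"):
            gid = gf.id
            gene_ids.add(gid)
            ann.genes.setdefault(gid, GeneRecord(gid, gf.seqid, gf.strand))
        for tf in db.all_features():
            if tf.featuretype not in TRANSCRIPT_TYPES:
                continue
            parents = tf.attributes.get("Parent", [])
            gid = parents[0] if parents else tf.id
            if gid not in ann.genes:
                ann.genes.setdefault(gid, GeneRecord(gid, tf.seqid, tf.strand))
            _register(ann, tid_to_gid, gid, tf.id, tf)
            declared_spans[tf.id] = _to_internal(tf)
        for kind in ("exon", "CDS"):
            for f in db.features_of_type(kind):
                parents = f.attributes.get("Parent")
                if not parents:
                    raise AnnotationError(
                        f"{kind} feature at {f.seqid}:{f.start}-{f.end} has no Parent")
                for tid in parents:
                    if tid not in tid_to_gid:
                        raise AnnotationError(
                            f"{kind} at {f.seqid}:{f.start}-{f.end} has unknown "
                            f"Parent {tid!r}")
                    _add_piece(ann, tid_to_gid, tid, kind, f, declared_spans)

    for gene in ann.genes.values():
        for t in gene.transcripts.values():
            t.exons = merge_intervals(t.exons)
            t.cds = merge_intervals(t.cds)
    return ann


def _register(ann, tid_to_gid, gid, tid, feature) -> None:
    gene = ann.genes.setdefault(gid, GeneRecord(gid, feature.seqid, feature.strand))
    if tid not in gene.transcripts:
        gene.transcripts[tid] = Transcript(tid, feature.strand, [], [])
    tid_to_gid[tid] = gid


def _add_piece(ann, tid_to_gid, tid, kind, feature, declared_spans) -> None:
    iv = _to_internal(feature)
    span = declared_spans.get(tid)
    if span is not None and (iv[0] < span[0] or iv[1] > span[1]):
        raise ValidationError(
            f"{kind} {feature.seqid}:{feature.start}-{feature.end} lies outside "
            f"the declared span of transcript {tid!r}")
    t = ann.genes[tid_to_gid[tid]].transcripts[tid]
    (t.exons if kind == "exon" else t.cds).append(iv)


def write_gtf(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write an annotation as GTF (1-based inclusive on output)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for tid in sorted(gene.transcripts):
                t = gene.transcripts[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                span = (min(s for s, _ in t.exons), max(e for _, e in t.exons))
                fh.write(_gtf_line(gene.chrom, "transcript", span, gene.strand, attrs))
                for iv in t.exons:
                    fh.write(_gtf_line(gene.chrom, "exon", iv, gene.strand, attrs))
                for iv in t.cds:
                    fh.write(_gtf_line(gene.chrom, "CDS", iv, gene.strand, attrs))


def _gtf_line(chrom, kind, iv, strand, attrs) -> str:
    return (f"{chrom}\tm6akit\t{kind}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# collapsing and filtering
# ---------------------------------------------------------------------------

def collapse_gene(gene: GeneRecord) -> GeneModel:
    """Collapse all transcripts of one gene into a single exon-union model.

    The CDS region is every exonic base between the outermost CDS boundaries
    over all transcripts; exonic bases 5' (transcript orientation) of it are
    the 5'UTR, those 3' of it the 3'UTR. A gene with no CDS on any transcript
    is returned non-coding with empty regions.
    """
    if not gene.transcripts:
        raise ValidationError(f"gene {gene.gene_id!r} has no transcripts")
    strands = {t.strand for t in gene.transcripts.values()} | {gene.strand}
    if len(strands) != 1:
        raise ValidationError(f"gene {gene.gene_id!r} mixes strands {sorted(strands)}")

    exons = merge_intervals(
        iv for t in gene.transcripts.values() for iv in t.exons)
    if not exons:
        raise ValidationError(f"gene {gene.gene_id!r} has no exons")
    cds_union = merge_intervals(
        iv for t in gene.transcripts.values() for iv in t.cds)

    if not cds_union:
        regions = {r: [] for r in REGIONS}
        return GeneModel(gene.gene_id, gene.chrom, gene.strand, exons,
                         regions, coding=False)

    cmin, cmax = cds_union[0][0], cds_union[-1][1]
    span = (exons[0][0], exons[-1][1])
    cds_region = intersect_intervals(exons, [(cmin, cmax)])
    left = intersect_intervals(exons, [(span[0], cmin)])
    right = intersect_intervals(exons, [(cmax, span[1])])
    if gene.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return GeneModel(gene.gene_id, gene.chrom, gene.strand, exons,
                     {"utr5": utr5, "cds": cds_region, "utr3": utr3})


def collapse_annotation(annotation: GenomeAnnotation) -> dict[str, GeneModel]:
    return {gid: collapse_gene(g) for gid, g in annotation.genes.items()}


def filter_models(models: Iterable[GeneModel], min_utr: int = 30,
                  min_cds: int = 100) -> ModelFilterReport:
    """Apply inclusion filters for metagene analysis.

    A gene is kept iff both UTRs are non-empty, each UTR is >= ``min_utr`` bp
    and the CDS is >= ``min_cds`` bp. Exclusions carry the first failing
    reason in the fixed order missing_utr, utr5_short, utr3_short, cds_short;
    non-coding genes fail missing_utr.
    """
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for m in models:
        lens = m.region_lengths
        if not m.coding or lens["utr5"] == 0 or lens["utr3"] == 0:
            excluded.append((m.gene_id, "missing_utr"))
        elif lens["utr5"] < min_utr:
            excluded.append((m.gene_id, "utr5_short"))
        elif lens["utr3"] < min_utr:
            excluded.append((m.gene_id, "utr3_short"))
        elif lens["cds"] < min_cds:
            excluded.append((m.gene_id, "cds_short"))
        else:
            kept.append(m.gene_id)
    return ModelFilterReport(kept, excluded)


def locate_position(model: GeneModel, genomic_pos: int,
                    chrom: str | None = None) -> PositionLabel:
    """Label a genomic position on a collapsed model.

    Returns the region and the spliced offset from the region's 5' end in
    transcript orientation; intronic/intergenic positions carry offset None.
    Exonic positions of non-coding genes are labeled ``exonic`` with the
    offset from the transcript 5' end.
    """
    if chrom is not None and chrom != model.chrom:
        raise ValueError(
            f"position on {chrom!r} but model {model.gene_id} is on {model.chrom!r}")
    span = model.span
    if genomic_pos < span[0] or genomic_pos >= span[1]:
        return PositionLabel("intergenic", None)
    if not any(s <= genomic_pos < e for s, e in model.exon_segments):
        return PositionLabel("intronic", None)
    for region in REGIONS:
        segs = model.region_segments[region]
        if any(s <= genomic_pos < e for s, e in segs):
            smap = SplicedMap(segs, model.strand)
            off = smap.genomic_to_spliced(genomic_pos, genomic_pos + 1)
            return PositionLabel(region, off[0])
    smap = SplicedMap(model.exon_segments, model.strand)
    off = smap.genomic_to_spliced(genomic_pos, genomic_pos + 1)
    return PositionLabel("exonic", off[0])


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_models_tsv(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """BED12-like TSV: one row per gene with region segment blocks."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tregion\tsegments\tlength\n")
        for m in models:
            for region in REGIONS:
                segs = m.region_segments[region]
                blocks = ",".join(f"{s}-{e}" for s, e in segs)
                fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{region}\t"
                         f"{blocks}\t{intervals_length(segs)}\n")


def write_filter_report_tsv(report: ModelFilterReport,
                            path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\treason\n")
        for gid in report.kept:
            fh.write(f"{gid}\tkept\t.\n")
        for gid, reason in report.excluded:
            fh.write(f"{gid}\texcluded\t{reason}\n")
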