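"""Metagene bin coverage, IP/input enrichment, profiles, heatmap matrices.

Each kept gene model is tiled with 30 bins over the 5'UTR, 100 over the CDS
and 30 over the 3'UTR, in transcript orientation. Reads overlapping a bin by
at least one exonic base increment that bin (a read spanning k bins counts in
all k). Counts are normalized to reads per million per bp:

    value = count / bin_width_bp / library_size * 1e6

so uniform per-base coverage gives identical values in all 160 bins despite
unequal bin widths. Replicates of one condition are combined by summing raw
counts and library sizes before the IP/input ratio is taken.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .gene_models import GeneModel, SplicedMap

#: default pseudocount added to normalized coverage before ratios
DEFAULT_PSEUDOCOUNT = 0.25

BIN_SCHEME = (30, 100, 30)


class AlignmentInputError(ValueError):
    pass


def bin_labels(n_utr5: int = 30, n_cds: int = 100, n_utr3: int = 30) -> list[str]:
    """Column labels U1..U30, C1..C100, D1..D30."""
    return ([f"U{i + 1}" for i in range(n_utr5)]
            + [f"C{i + 1}" for i in range(n_cds)]
            + [f"D{i + 1}" for i in range(n_utr3)])


# ---------------------------------------------------------------------------
# read containers
# ---------------------------------------------------------------------------

@dataclass
class ChromReads:
    """Aligned read blocks on one chromosome, flattened for vector ops."""
    block_start: np.ndarray
    block_end: np.ndarray
    read_id: np.ndarray
    n_reads: int
    max_block: int


@dataclass
class ReadSet:
    """A library of spliced single-end alignments, grouped by chromosome."""
    sample_id: str
    chroms: dict[str, ChromReads] = field(default_factory=dict)
    n_reads: int = 0   # library size: total mapped reads


def _build_chrom(blocks: list[tuple[int, int, int]], n_reads: int) -> ChromReads:
    arr = np.asarray(blocks, dtype=np.int64).reshape(-1, 3)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    max_block = int((arr[:, 1] - arr[:, 0]).max()) if len(arr) else 0
    return ChromReads(arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy(),
                      n_reads, max_block)


def read_sam(path: str | os.PathLike, sample_id: str | None = None) -> ReadSet:
    """Load a coordinate-sorted SAM/BAM into a :class:`ReadSet`.

    Spliced alignments contribute one block per aligned segment
    (``get_blocks``). Unmapped reads are skipped but the file must be
    coordinate-sorted.
    """
    sample_id = sample_id or os.path.basename(str(path))
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        so = (fh.header.get("HD") or {}).get("SO", "unknown")
        if so != "coordinate":
            raise AlignmentInputError(
                f"{path}: sort order is {so!r}; coordinate-sorted input required "
                "(run `samtools sort` and, for BAM, `samtools index`)")
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        counts: dict[str, int] = {}
        total = 0
        for rec in fh:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            rid = counts.get(chrom, 0)
            counts[chrom] = rid + 1
            total += 1
            blocks = per_chrom.setdefault(chrom, [])
            for s, e in rec.get_blocks():
                blocks.append((s, e, rid))
    rs = ReadSet(sample_id, {}, total)
    for chrom, blocks in per_chrom.items():
        rs.chroms[chrom] = _build_chrom(blocks, counts[chrom])
    return rs


def read_bed_reads(path: str | os.PathLike, sample_id: str | None = None) -> ReadSet:
    """Load the BED6 read dialect: chrom, start, end, read_name, score, strand.

    Consecutive lines sharing a read name are the spliced blocks of one read.
    """
    sample_id = sample_id or os.path.basename(str(path))
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    counts: dict[str, int] = {}
    last: tuple[str, str] | None = None
    total = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise AlignmentInputError(f"{path}:{ln}: expected >=4 BED columns")
            chrom, s, e, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            key = (chrom, name)
            if key != last:
                counts[chrom] = counts.get(chrom, 0) + 1
                total += 1
                last = key
            per_chrom.setdefault(chrom, []).append((s, e, counts[chrom] - 1))
    rs = ReadSet(sample_id, {}, total)
    for chrom, blocks in per_chrom.items():
        rs.chroms[chrom] = _build_chrom(blocks, counts[chrom])
    return rs


def merge_readsets(readsets: Sequence[ReadSet], sample_id: str = "pooled") -> ReadSet:
    """Pool replicate libraries into one ReadSet (counts and sizes add)."""
    merged = ReadSet(sample_id, {}, sum(r.n_reads for r in readsets))
    chroms = sorted({c for r in readsets for c in r.chroms})
    for chrom in chroms:
        blocks = []
        offset = 0
        n_reads = 0
        for r in readsets:
            cr = r.chroms.get(chrom)
            if cr is None:
                continue
            for s, e, rid in zip(cr.block_start, cr.block_end, cr.read_id):
                blocks.append((int(s), int(e), int(rid) + offset))
            offset += cr.n_reads
            n_reads += cr.n_reads
        merged.chroms[chrom] = _build_chrom(blocks, n_reads)
    return merged


def load_reads(path: str | os.PathLike, sample_id: str | None = None) -> ReadSet:
    """Dispatch on extension: .sam/.bam via pysam, .bed via the read dialect."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".sam", ".bam"):
        return read_sam(path, sample_id)
    if ext == ".bed":
        return read_bed_reads(path, sample_id)
    raise AlignmentInputError(f"unrecognized alignment extension {ext!r}")


# ---------------------------------------------------------------------------
# bin grids
# ---------------------------------------------------------------------------

@dataclass
class BinGrid:
    """Metagene bin boundaries for one gene, transcript orientation.

    ``boundaries`` has n_bins+1 offsets into the spliced transcript
    coordinate (5'UTR, then CDS, then 3'UTR). When a region length is not
    divisible by its bin count the remainder goes to the first (most 5')
    bins, so widths within a region differ by at most 1 bp.
    """
    gene_id: str
    n_utr5: int
    n_cds: int
    n_utr3: int
    boundaries: np.ndarray     # int64, len n_bins + 1
    splice_map: SplicedMap     # over the gene's exon segments

    @property
    def n_bins(self) -> int:
        return self.n_utr5 + self.n_cds + self.n_utr3

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def region_bin_slices(self) -> dict[str, slice]:
        a, b = self.n_utr5, self.n_utr5 + self.n_cds
        return {"utr5": slice(0, a), "cds": slice(a, b),
                "utr3": slice(b, b + self.n_utr3)}


def _tile(length: int, n: int) -> np.ndarray:
    base, rem = divmod(length, n)
    w = np.full(n, base, dtype=np.int64)
    w[:rem] += 1          # longer bins first, transcript orientation
    return w


def make_grid(model: GeneModel, n_utr5: int = 30, n_cds: int = 100,
              n_utr3: int = 30) -> BinGrid:
    """Tile a filtered gene model into evenly spaced metagene bins."""
    lens = model.region_lengths
    for region, n in (("utr5", n_utr5), ("cds", n_cds), ("utr3", n_utr3)):
        if lens[region] < n:
            raise ValueError(
                f"gene {model.gene_id}: {region} length {lens[region]} bp "
                f"cannot be tiled in {n} bins")
    widths = np.concatenate([_tile(lens["utr5"], n_utr5),
                             _tile(lens["cds"], n_cds),
                             _tile(lens["utr3"], n_utr3)])
    boundaries = np.concatenate([[0], np.cumsum(widths)])
    return BinGrid(model.gene_id, n_utr5, n_cds, n_utr3, boundaries,
                   SplicedMap(model.exon_segments, model.strand))


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _spliced_read_intervals(creads: ChromReads, lo: int, hi: int,
                            smap: SplicedMap, gene_span: tuple[int, int]):
    """Transcript-oriented spliced intervals per read for blocks[lo:hi].

    Returns (read ids, interval starts, interval ends); a read with several
    blocks whose spliced images are non-adjacent yields several rows.
    """
    bs = creads.block_start[lo:hi]
    be = creads.block_end[lo:hi]
    rid = creads.read_id[lo:hi]
    keep = (be > gene_span[0]) & (bs < gene_span[1])
    bs, be, rid = bs[keep], be[keep], rid[keep]
    if len(bs) == 0:
        return rid, bs, be
    a = smap.rank(bs)
    b = smap.rank(be)
    nz = b > a
    a, b, rid = a[nz], b[nz], rid[nz]
    if len(a) == 0:
        return rid, a, b
    if smap.strand == "-":
        a, b = smap.length - b, smap.length - a
    # merge blocks of one read; images of intron-separated blocks are
    # adjacent in spliced space, so a plain sorted sweep suffices
    order = np.lexsort((a, rid))
    a, b, rid = a[order], b[order], rid[order]
    starts, ends, rids = [], [], []
    cur_r, cur_a, cur_b = int(rid[0]), int(a[0]), int(b[0])
    for r, x, y in zip(rid[1:], a[1:], b[1:]):
        if r == cur_r and x <= cur_b:
            cur_b = max(cur_b, int(y))
        else:
            rids.append(cur_r); starts.append(cur_a); ends.append(cur_b)
            cur_r, cur_a, cur_b = int(r), int(x), int(y)
    rids.append(cur_r); starts.append(cur_a); ends.append(cur_b)
    return (np.asarray(rids, dtype=np.int64),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64))


def spliced_read_intervals(reads: ReadSet, model: GeneModel,
                           smap: SplicedMap | None = None):
    """Merged transcript-oriented spliced intervals of reads over one gene.

    Returns (read ids, starts, ends); most reads yield one interval.
    """
    smap = smap or SplicedMap(model.exon_segments, model.strand)
    empty = np.empty(0, dtype=np.int64)
    creads = reads.chroms.get(model.chrom)
    if creads is None or len(creads.block_start) == 0:
        return empty, empty, empty
    span = model.span
    lo = int(np.searchsorted(creads.block_start, span[0] - creads.max_block))
    hi = int(np.searchsorted(creads.block_start, span[1]))
    return _spliced_read_intervals(creads, lo, hi, smap, span)


def accumulate_range_counts(rid: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                            n: int) -> np.ndarray:
    """Count, per slot 0..n-1, the reads whose index range [lo, hi) covers it.

    A read contributing several ranges is counted at most once per slot.
    """
    counts = np.zeros(n, dtype=np.int64)
    if len(lo) == 0:
        return counts
    diff = np.zeros(n + 1, dtype=np.int64)
    if len(np.unique(rid)) == len(rid):
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
    else:
        seen: dict[int, list[tuple[int, int]]] = {}
        for r, l, h in zip(rid, lo, hi):
            seen.setdefault(int(r), []).append((int(l), int(h)))
        for ranges in seen.values():
            ranges.sort()
            cl, ch = ranges[0]
            merged = []
            for l, h in ranges[1:]:
                if l <= ch:
                    ch = max(ch, h)
                else:
                    merged.append((cl, ch))
                    cl, ch = l, h
            merged.append((cl, ch))
            for l, h in merged:
                diff[l] += 1
                diff[h] -= 1
    counts += np.cumsum(diff[:-1])
    return counts


def count_bin_reads(reads: ReadSet, model: GeneModel, grid: BinGrid) -> np.ndarray:
    """Raw read counts per metagene bin for one gene.

    A read increments every bin whose genomic footprint it overlaps by at
    least one exonic base; intronic-only reads count nowhere; a read is
    counted at most once per bin.
    """
    rid, a, b = spliced_read_intervals(reads, model, grid.splice_map)
    if len(a) == 0:
        return np.zeros(grid.n_bins, dtype=np.int64)
    bounds = grid.boundaries
    blo = np.maximum(np.searchsorted(bounds, a, side="right") - 1, 0)
    bhi = np.minimum(np.searchsorted(bounds, b, side="left"), grid.n_bins)
    ok = bhi > blo
    return accumulate_range_counts(rid[ok], blo[ok], bhi[ok], grid.n_bins)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class BinCoverageMatrix:
    """Genes x bins normalized coverage for one library."""
    sample_id: str
    genes: list[str]
    raw_counts: np.ndarray     # int64, genes x bins
    bin_widths: np.ndarray     # int64, genes x bins
    library_size: int
    values: np.ndarray = field(init=False)   # reads per million per bp

    def __post_init__(self) -> None:
        self.values = normalize_values(self.raw_counts, self.bin_widths,
                                       self.library_size)


@dataclass
class EnrichmentMatrix:
    """Genes x bins IP/input ratio after replicate summation."""
    condition: str
    genes: list[str]
    values: np.ndarray
    pseudocount: float


def normalize_values(raw_counts: np.ndarray, widths: np.ndarray,
                     library_size: int) -> np.ndarray:
    """count / bin width / library size * 1e6, elementwise."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return raw_counts / widths / library_size * 1e6


def count_matrix(reads: ReadSet, models: dict[str, GeneModel],
                 grids: dict[str, BinGrid]) -> BinCoverageMatrix:
    """Count and normalize one library over all gridded genes."""
    genes = sorted(grids)
    raw = np.zeros((len(genes), next(iter(grids.values())).n_bins), dtype=np.int64)
    widths = np.zeros_like(raw)
    for i, gid in enumerate(genes):
        raw[i] = count_bin_reads(reads, models[gid], grids[gid])
        widths[i] = grids[gid].widths
    return BinCoverageMatrix(reads.sample_id, genes, raw, widths, reads.n_reads)


def normalize_bins(raw_counts: np.ndarray, grid: BinGrid,
                   library_size: int) -> np.ndarray:
    """Normalize one gene's raw bin counts (single-gene convenience)."""
    return normalize_values(raw_counts, grid.widths, library_size)


def enrichment(ip: Sequence[BinCoverageMatrix],
               input_: Sequence[BinCoverageMatrix],
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               condition: str = "") -> EnrichmentMatrix:
    """IP/input ratio after summing replicate counts and library sizes.

    Raw counts of replicates of each sample type are summed per bin, the sums
    renormalized with the summed library sizes, then the ratio
    (ip + pc) / (input + pc) taken per bin.
    """
    if not ip or not input_:
        raise ValueError("need at least one IP and one input replicate")
    ref = ip[0]
    for m in list(ip) + list(input_):
        if m.genes != ref.genes:
            missing = sorted(set(ref.genes) ^ set(m.genes))
            raise ValueError(f"replicate gene sets differ; offenders: {missing[:10]}")
    ip_raw = sum(m.raw_counts for m in ip)
    in_raw = sum(m.raw_counts for m in input_)
    ip_lib = sum(m.library_size for m in ip)
    in_lib = sum(m.library_size for m in input_)
    ip_norm = normalize_values(ip_raw, ref.bin_widths, ip_lib)
    in_norm = normalize_values(in_raw, ref.bin_widths, in_lib)
    values = (ip_norm + pseudocount) / (in_norm + pseudocount)
    return EnrichmentMatrix(condition, list(ref.genes), values, pseudocount)


def metagene_profile(matrix: BinCoverageMatrix | EnrichmentMatrix
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean across genes and the per-bin gene count used.

    Non-finite entries (zero-input bins without pseudocount) are excluded
    bin-wise from the mean.
    """
    values = matrix.values
    if values.shape[0] == 0:
        raise ValueError("empty matrix")
    finite = np.isfinite(values)
    n = finite.sum(axis=0)
    total = np.where(finite, values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        profile = np.where(n > 0, total / n, np.nan)
    return profile, n


def region_mean(matrix: BinCoverageMatrix | EnrichmentMatrix, region: str,
                scheme: tuple[int, int, int] = BIN_SCHEME) -> np.ndarray:
    """Per-gene mean over one region's bins (e.g. mean 5'UTR enrichment)."""
    a, b, c = scheme
    sl = {"utr5": slice(0, a), "cds": slice(a, a + b),
          "utr3": slice(a + b, a + b + c)}[region]
    return matrix.values[:, sl].mean(axis=1)


def zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (mean 0, sample sd 1, n-1 denominator) for heatmaps.

    Constant rows cannot be scaled; they are emitted as zeros and flagged.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    return z, constant


# ---------------------------------------------------------------------------
# per-base tracks
# ---------------------------------------------------------------------------

def log_ratio_track(ip_coverage: np.ndarray, input_coverage: np.ndarray,
                    ip_library_size: int, input_library_size: int,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Per-base log2(IP/input) after CPM normalization of each library."""
    ip_coverage = np.asarray(ip_coverage, dtype=float)
    input_coverage = np.asarray(input_coverage, dtype=float)
    if ip_coverage.shape != input_coverage.shape:
        raise ValueError("IP and input coverage spans differ")
    ip_cpm = ip_coverage / ip_library_size * 1e6
    in_cpm = input_coverage / input_library_size * 1e6
    return np.log2((ip_cpm + pseudocount) / (in_cpm + pseudocount))


def write_bedgraph(track: np.ndarray, chrom: str, start: int,
                   path: str | os.PathLike) -> None:
    """Write a per-base track as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        if len(track) == 0:
            return
        run_start = 0
        for i in range(1, len(track) + 1):
            if i == len(track) or track[i] != track[run_start]:
                fh.write(f"{chrom}\t{start + run_start}\t{start + i}\t"
                         f"{track[run_start]:.6g}\n")
                run_start = i


# ---------------------------------------------------------------------------
# paired comparison of region enrichment
# ---------------------------------------------------------------------------

class PairedTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def paired_region_test(values_a: Sequence[float],
                       values_b: Sequence[float]) -> PairedTestResult:
    """Paired two-tailed t-test on per-gene region means of two conditions.

    Identical vectors (zero-variance differences centred on 0) return t = 0,
    p = 1; constant non-zero differences return an infinite t with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition vectors must share gene ordering and length")
    n = len(a)
    if n < 3:
        raise ValueError(f"paired t-test needs n >= 3 genes, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(0.0, n - 1, 1.0)
        return PairedTestResult(math.copysign(math.inf, d.mean()), n - 1, 0.0)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), n - 1, float(res.pvalue))


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def matrix_to_frame(matrix: BinCoverageMatrix | EnrichmentMatrix) -> pd.DataFrame:
    n = matrix.values.shape[1]
    labels = bin_labels(*BIN_SCHEME) if n == sum(BIN_SCHEME) else [
        f"B{i + 1}" for i in range(n)]
    return pd.DataFrame(matrix.values, index=pd.Index(matrix.genes, name="gene_id"),
                        columns=labels)


def write_matrix_tsv(matrix: BinCoverageMatrix | EnrichmentMatrix,
                     path: str | os.PathLike) -> None:
    matrix_to_frame(matrix).to_csv(path, sep="\t", float_format="%.6g")


def write_profile_tsv(profile: np.ndarray, n_genes: np.ndarray,
                      path: str | os.PathLike) -> None:
    labels = bin_labels(*BIN_SCHEME) if len(profile) == sum(BIN_SCHEME) else [
        f"B{i + 1}" for i in range(len(profile))]
    pd.DataFrame({"bin": labels, "mean": profile, "n_genes": n_genes}
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")
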