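"""Peak calling, region assignment and Mettl3-dependence calling.

The peak caller is a deliberately simple, exactly specified surrogate for
HMM-based MeRIP peak callers: sliding windows over the spliced exonic
sequence of each gene are tested with a one-sided binomial test of the IP
read count against the proportion expected from the input count and the two
library sizes, Benjamini-Hochberg corrected, and maximal runs of significant
windows are merged into peaks.

Differential methylation between genotypes follows the published thresholds
of RADAR-style analyses (bin count filter 15, adjusted p < 0.05, beta cutoff
0.5, log2 fold change < -1 for loss in the knockdown) on top of a surrogate
statistic: the replicate-level methylation level of a 50-bp exonic bin,
m = log2((ip_cpm + pc) / (input_cpm + pc)), compared between conditions with
a Welch t-test.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage_metagene import (DEFAULT_PSEUDOCOUNT, ReadSet,
                                accumulate_range_counts,
                                spliced_read_intervals)
from .gene_models import (GeneModel, REGIONS, SplicedMap, intersect_intervals,
                          intervals_length)

#: fixed tie-break priority for region assignment
REGION_PRIORITY = ("utr5", "cds", "utr3")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    gene_id: str
    score: float                 # -log10 adjusted p
    enrichment: float            # pooled IP/input cpm ratio over the peak
    assigned_region: str = "unassigned"
    spliced_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end} is empty")


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class DiffMethylResult:
    gene_id: str
    bin_index: int
    chrom: str
    start: int                   # genomic span of the bin
    end: int
    beta: float                  # mean difference of m, treatment - control
    p: float
    p_adj: float
    passes_count_filter: bool
    dependent: bool


# ---------------------------------------------------------------------------
# window counting
# ---------------------------------------------------------------------------

def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Starts of sliding windows covering spliced [0, length)."""
    if length <= window:
        return np.array([0], dtype=np.int64)
    starts = np.arange(0, length - window + 1, step, dtype=np.int64)
    if starts[-1] + window < length:
        starts = np.append(starts, length - window)
    return starts


def window_read_counts(reads: ReadSet, model: GeneModel, window: int,
                       step: int, smap: SplicedMap | None = None) -> np.ndarray:
    """Reads overlapping each sliding window by >=1 exonic bp."""
    smap = smap or SplicedMap(model.exon_segments, model.strand)
    starts = window_starts(smap.length, window, step)
    rid, a, b = spliced_read_intervals(reads, model, smap)
    if len(a) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    # window k overlaps read interval [a, b) iff starts[k] in (a - window, b)
    lo = np.searchsorted(starts, a - window, side="right")
    hi = np.searchsorted(starts, b, side="left")
    ok = hi > lo
    return accumulate_range_counts(rid[ok], lo[ok], hi[ok], len(starts))


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def call_peaks(ip_reads: ReadSet, input_reads: ReadSet,
               models: dict[str, GeneModel], window: int = 50,
               step: int = 25, alpha: float = 0.05,
               min_enrichment: float = 2.0,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PeakSet:
    """Call IP-over-input enriched peaks on the exonic sequence of each gene.

    Per window, the IP count x out of n = x + y (y the input count) is tested
    against the null proportion p0 = N_ip / (N_ip + N_input) implied by the
    library sizes with a one-sided binomial test; BH correction is applied
    across all windows of all genes; runs of significant enriched windows are
    merged and reported with pooled enrichment and the run's minimum
    adjusted p. As in standard MeRIP peak callers, a window must also show
    at least ``min_enrichment``-fold library-normalized IP/input enrichment
    to enter a peak — statistical significance alone admits shallow
    fluctuations at high coverage.
    """
    if input_reads.n_reads <= 0:
        raise ValueError("input library is empty")
    if ip_reads.n_reads <= 0:
        raise ValueError("IP library is empty")
    p0 = ip_reads.n_reads / (ip_reads.n_reads + input_reads.n_reads)

    per_gene: list[tuple[str, SplicedMap, np.ndarray, np.ndarray, np.ndarray]] = []
    pvals: list[np.ndarray] = []
    for gid in sorted(models):
        model = models[gid]
        smap = SplicedMap(model.exon_segments, model.strand)
        starts = window_starts(smap.length, window, step)
        x = window_read_counts(ip_reads, model, window, step, smap)
        y = window_read_counts(input_reads, model, window, step, smap)
        n = x + y
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.binom.sf(x - 1, n, p0)
        p = np.where(n == 0, 1.0, p)
        per_gene.append((gid, smap, starts, x, y))
        pvals.append(p)

    flat = np.concatenate(pvals) if pvals else np.empty(0)
    if len(flat) == 0:
        return PeakSet([])
    p_adj = multipletests(flat, method="fdr_bh")[1]

    peaks: list[Peak] = []
    offset = 0
    for (gid, smap, starts, x, y), p in zip(per_gene, pvals):
        padj = p_adj[offset:offset + len(p)]
        offset += len(p)
        ratio = ((x / ip_reads.n_reads * 1e6 + pseudocount)
                 / (y / input_reads.n_reads * 1e6 + pseudocount))
        enriched = (padj < alpha) & (ratio >= min_enrichment)
        model = models[gid]
        for run in _runs(enriched):
            lo, hi = run
            sp_start = int(starts[lo])
            sp_end = int(min(starts[hi - 1] + window, smap.length))
            segs = smap.spliced_to_genomic(sp_start, sp_end)
            g_start = min(s for s, _ in segs)
            g_end = max(e for _, e in segs)
            rid, a, b = spliced_read_intervals(ip_reads, model, smap)
            ip_n = int(np.sum((b > sp_start) & (a < sp_end)))
            rid, a, b = spliced_read_intervals(input_reads, model, smap)
            in_n = int(np.sum((b > sp_start) & (a < sp_end)))
            enr = ((ip_n / ip_reads.n_reads * 1e6 + pseudocount)
                   / (in_n / input_reads.n_reads * 1e6 + pseudocount))
            score = float(-np.log10(max(padj[lo:hi].min(), 1e-300)))
            peaks.append(Peak(model.chrom, g_start, g_end, gid, score, enr,
                              spliced_interval=(sp_start, sp_end)))
    return PeakSet(peaks)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [lo, hi) index pairs."""
    runs = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            lo, in_run = i, True
        elif not v and in_run:
            runs.append((lo, i))
            in_run = False
    if in_run:
        runs.append((lo, len(mask)))
    return runs


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def assign_peak_region(peak: Peak, model: GeneModel,
                       priority: Sequence[str] = REGION_PRIORITY) -> str:
    """Assign a peak to the region holding most of its exonic footprint.

    The peak's genomic interval is intersected with each region's segments;
    the region with the largest overlap wins; exact ties are broken by the
    fixed priority 5'UTR > CDS > 3'UTR. A peak with no exonic overlap is
    left unassigned with a warning.
    """
    iv = [(peak.start, peak.end)]
    overlaps = {r: intervals_length(intersect_intervals(model.region_segments[r], iv))
                for r in REGIONS}
    best = max(overlaps.values())
    if best == 0:
        warnings.warn(f"peak {peak.chrom}:{peak.start}-{peak.end} has no exonic "
                      f"overlap with {model.gene_id}; left unassigned")
        peak.assigned_region = "unassigned"
        return peak.assigned_region
    for region in priority:
        if overlaps[region] == best:
            peak.assigned_region = region
            return region
    raise AssertionError("unreachable")


def assign_all(peakset: PeakSet, models: dict[str, GeneModel]) -> PeakSet:
    for peak in peakset:
        model = models.get(peak.gene_id)
        if model is not None:
            assign_peak_region(peak, model)
    return peakset


def region_distribution(peakset: PeakSet) -> dict[str, dict[str, float]]:
    """Counts and percentages of assigned peaks per region."""
    assigned = [p for p in peakset if p.assigned_region in REGIONS]
    if not assigned:
        raise ValueError("no assigned peaks")
    out = {}
    for region in REGIONS:
        n = sum(1 for p in assigned if p.assigned_region == region)
        out[region] = {"count": n, "percent": 100.0 * n / len(assigned)}
    return out


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

def differential_methylation(
        control: Sequence[tuple[ReadSet, ReadSet]],
        treatment: Sequence[tuple[ReadSet, ReadSet]],
        models: dict[str, GeneModel],
        bin_size: int = 50, min_count: int = 15, alpha: float = 0.05,
        beta_cutoff: float = 0.5, lfc_cutoff: float = 1.0,
        variance: str = "moderated",
        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[DiffMethylResult]:
    """Per-bin test of replicate methylation levels between genotypes.

    ``control`` and ``treatment`` are sequences of (IP, input) read-set pairs,
    one per replicate. Exonic 50-bp bins with summed raw IP count below
    ``min_count`` in either condition are excluded before testing. A bin is
    called *dependent* (Mettl3-dependent loss) when adjusted p < ``alpha``,
    |beta| >= ``beta_cutoff`` and beta <= -``lfc_cutoff`` (log2 loss from
    control to treatment).

    ``variance`` selects the test: ``"moderated"`` (default) shrinks each
    bin's pooled variance toward an empirical-Bayes prior fitted across all
    tested bins, gaining the degrees of freedom a 2-3 replicate design lacks;
    ``"welch"`` is the plain two-sample Welch t-test.
    """
    if len(control) < 2 or len(treatment) < 2:
        raise ValueError("need >=2 replicates per condition")

    gene_ids = sorted(models)
    rows: list[dict] = []
    for gid in gene_ids:
        model = models[gid]
        smap = SplicedMap(model.exon_segments, model.strand)
        starts = window_starts(smap.length, bin_size, bin_size)
        nw = len(starts)
        ctrl_m = np.empty((len(control), nw))
        trt_m = np.empty((len(treatment), nw))
        ctrl_ip_sum = np.zeros(nw, dtype=np.int64)
        trt_ip_sum = np.zeros(nw, dtype=np.int64)
        for arr, ip_sum, pairs in ((ctrl_m, ctrl_ip_sum, control),
                                   (trt_m, trt_ip_sum, treatment)):
            for r, (ip_rs, in_rs) in enumerate(pairs):
                ip = window_read_counts(ip_rs, model, bin_size, bin_size, smap)
                inp = window_read_counts(in_rs, model, bin_size, bin_size, smap)
                ip_cpm = ip / ip_rs.n_reads * 1e6
                in_cpm = inp / in_rs.n_reads * 1e6
                arr[r] = np.log2((ip_cpm + pseudocount) / (in_cpm + pseudocount))
                ip_sum += ip
        for k in range(nw):
            sp = (int(starts[k]), int(min(starts[k] + bin_size, smap.length)))
            segs = smap.spliced_to_genomic(*sp)
            g0 = min(s for s, _ in segs)
            g1 = max(e for _, e in segs)
            rows.append(dict(
                gene_id=gid, bin_index=k, chrom=model.chrom, start=g0, end=g1,
                ctrl=ctrl_m[:, k], trt=trt_m[:, k],
                passes=bool(ctrl_ip_sum[k] >= min_count
                            and trt_ip_sum[k] >= min_count)))

    tested = [r for r in rows if r["passes"]]
    if not tested:
        warnings.warn("all bins removed by the count filter; empty result")
    if variance == "moderated":
        pvals = _moderated_test(tested)
    elif variance == "welch":
        pvals = _welch_test(tested)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    padj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    for r, pa in zip(tested, padj):
        r["p_adj"] = float(pa)

    results = []
    for r in rows:
        if r["passes"]:
            dependent = (r["p_adj"] < alpha and abs(r["beta"]) >= beta_cutoff
                         and r["beta"] <= -lfc_cutoff)
            results.append(DiffMethylResult(
                r["gene_id"], r["bin_index"], r["chrom"], r["start"], r["end"],
                r["beta"], r["p"], r["p_adj"], True, dependent))
        else:
            results.append(DiffMethylResult(
                r["gene_id"], r["bin_index"], r["chrom"], r["start"], r["end"],
                float("nan"), float("nan"), float("nan"), False, False))
    return results


def _welch_test(tested: list[dict]) -> list[float]:
    """Plain Welch t-test per bin; zero-variance bins documented as p=1/0."""
    pvals = []
    for r in tested:
        beta = float(r["trt"].mean() - r["ctrl"].mean())
        r["beta"] = beta
        if r["trt"].std(ddof=1) == 0 and r["ctrl"].std(ddof=1) == 0:
            p = 1.0 if beta == 0 else 0.0
        else:
            p = float(stats.ttest_ind(r["trt"], r["ctrl"], equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        r["p"] = p
        pvals.append(p)
    return pvals


def _trigamma_inverse(z: float) -> float:
    """Solve trigamma(y) = z for y > 0 (Newton, monotone decreasing)."""
    from scipy.special import polygamma
    if z > 1e7:
        return 1.0 / math.sqrt(z)
    if z < 1e-6:
        return 1.0 / z
    y = 0.5 + 1.0 / z
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / z) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _moderated_test(tested: list[dict]) -> list[float]:
    """Empirical-Bayes moderated t across bins (variance shrinkage).

    Pooled per-bin variances are shrunk toward a scaled inverse-chi-square
    prior whose scale s0^2 and degrees of freedom d0 are fitted by moments
    on log variances; the moderated t has d + d0 degrees of freedom.
    """
    from scipy.special import digamma, polygamma
    if not tested:
        return []
    nt = len(tested[0]["trt"])
    nc = len(tested[0]["ctrl"])
    d = nt + nc - 2
    betas = np.array([float(r["trt"].mean() - r["ctrl"].mean()) for r in tested])
    s2 = np.array([
        (np.sum((r["trt"] - r["trt"].mean()) ** 2)
         + np.sum((r["ctrl"] - r["ctrl"].mean()) ** 2)) / d for r in tested])
    pos = s2 > 0
    if pos.sum() >= 2:
        e = np.log(s2[pos]) - float(digamma(d / 2)) + math.log(d / 2)
        evar = float(np.var(e, ddof=1))
        target = evar - float(polygamma(1, d / 2))
        if target > 0:
            d0 = 2.0 * _trigamma_inverse(target)
            log_s0 = float(np.mean(e)) + float(digamma(d0 / 2)) - math.log(d0 / 2)
        else:
            d0 = math.inf
            log_s0 = float(np.mean(e))
        s0_sq = math.exp(log_s0)
    else:
        d0, s0_sq = math.inf, float(s2[pos].mean()) if pos.any() else 1e-8
    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_mod * (1.0 / nt + 1.0 / nc))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(p), p, 1.0)
    pvals = []
    for r, beta, pv in zip(tested, betas, p):
        r["beta"] = float(beta)
        r["p"] = float(pv)
        pvals.append(float(pv))
    return pvals


def m6a_gene_set(results: Iterable[DiffMethylResult]) -> list[str]:
    """Genes with at least one dependent bin, deduplicated, sorted."""
    return sorted({r.gene_id for r in results if r.dependent})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_peaks_bed(peakset: PeakSet, path: str | os.PathLike) -> None:
    """BED6 plus enrichment and assigned region columns."""
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peakset, key=lambda q: (q.chrom, q.start,
                                                             q.end, q.gene_id))):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}.peak{i + 1}\t"
                     f"{p.score:.4f}\t+\t{p.enrichment:.4f}\t{p.assigned_region}\n")


def read_peaks_bed(path: str | os.PathLike) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            gene = f[3].rsplit(".peak", 1)[0] if len(f) > 3 else ""
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), gene,
                              float(f[4]) if len(f) > 4 else 0.0,
                              float(f[6]) if len(f) > 6 else float("nan"),
                              f[7] if len(f) > 7 else "unassigned"))
    return PeakSet(peaks)


def write_diffmeth_tsv(results: Sequence[DiffMethylResult],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbin_index\tchrom\tstart\tend\tbeta\tp\tp_adj\t"
                 "passes_count_filter\tdependent\n")
        for r in results:
            fh.write(f"{r.gene_id}\t{r.bin_index}\t{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.beta:.6g}\t{r.p:.6g}\t{r.p_adj:.6g}\t"
                     f"{int(r.passes_count_filter)}\t{int(r.dependent)}\n")
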