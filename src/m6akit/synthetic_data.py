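"""Synthetic MeRIP-seq experiment generator with ground truth.

Emulates the design of an m6A-IP sequencing study in fly heads at desk
scale: a toy multi-chromosome transcriptome with 1-3 isoforms per gene,
planted methylation peaks placed overwhelmingly in 5'UTRs, IP/input read
pairs whose IP rate is multiplied by an enrichment fold gamma inside planted
peaks, a methyltransferase-knockdown genotype that erases dependent peaks
(gamma -> 1), a heat-shock condition that boosts 5'UTR peak enrichment,
differential-expression tables with an up-regulation skew for modified
genes, and exponential decay series with condition-dependent half-lives.
Every draw is reproducible from an integer seed, and the planted truth is
returned alongside for parameter-recovery tests.

Default study conditions follow the experimental design being emulated:
three biological replicates per genotype and condition, ~30x per-base input
coverage, 14.1% of expressed genes modified, peak placement weighted
(0.9, 0.07, 0.03) over (5'UTR, CDS, 3'UTR), and decay sampled at
0, 0.5, 1, 2 and 4 h.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .coverage_metagene import ChromReads, ReadSet, _build_chrom
from .gene_models import (GeneModel, GeneRecord, GenomeAnnotation, SplicedMap,
                          Transcript, collapse_annotation, write_gtf)
from .set_stats import reverse_complement

CONDITIONS = ("basal", "HS")
GENOTYPES = ("control", "knockdown")
DECAY_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""
    n_genes: int = 50
    genes_per_chromosome: int = 25
    utr5_len: tuple[int, int] = (60, 600)
    cds_len: tuple[int, int] = (300, 3000)
    utr3_len: tuple[int, int] = (60, 600)
    intron_len: tuple[int, int] = (60, 200)
    max_exons: int = 3
    max_transcripts: int = 3
    intergenic_gap: int = 500
    # planted methylation
    fraction_modified: float = 0.141
    region_weights: tuple[float, float, float] = (0.9, 0.07, 0.03)
    peak_len: tuple[int, int] = (100, 200)
    gamma: float = 8.0
    hs_utr5_factor: float = 1.5
    fraction_dependent: float = 1.0     # planted peaks erased by knockdown
    motif: str = "GGACT"
    motif_incidence: float = 0.6
    # sequencing
    depth: float = 30.0                 # mean per-base input coverage
    read_length: int = 100
    n_replicates: int = 3
    expression_sigma: float = 0.5       # lognormal spread of gene expression
    # filter-violation planting (fractions of genes per rule)
    violation_fractions: dict = field(default_factory=dict)
    # DE skew
    p_directed: float = 0.5
    p_up_modified: float = 0.8
    p_up_unmodified: float = 0.4
    lfc_sigma: float = 0.6
    # decay
    half_life_control: float = 1.0      # hours
    half_life_knockdown: float = 4.0
    decay_noise_cv: float = 0.10
    decay_replicates: int = 6

    def validate(self) -> "SimulationConfig":
        if self.n_genes <= 0 or self.depth <= 0:
            raise ValueError("n_genes and depth must be positive")
        w = np.asarray(self.region_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("region weights must be non-negative and sum to 1")
        for p in (self.fraction_modified, self.p_directed, self.p_up_modified,
                  self.p_up_unmodified, self.fraction_dependent,
                  self.motif_incidence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for name in ("utr5_len", "cds_len", "utr3_len", "intron_len",
                     "peak_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible length range {name}={lo, hi}")
        return self


@dataclass
class PlantedPeak:
    gene_id: str
    chrom: str
    start: int                     # genomic span (may cross introns)
    end: int
    region: str
    spliced_interval: tuple[int, int]   # transcript coordinates
    gamma: float
    dependent: bool


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests."""
    modified: dict[str, bool] = field(default_factory=dict)
    peaks: list[PlantedPeak] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    violations: dict[str, str] = field(default_factory=dict)  # gene -> rule
    de_direction: dict[str, dict[str, str]] = field(default_factory=dict)
    half_life: dict[str, dict[str, float]] = field(default_factory=dict)

    def peaks_of(self, gene_id: str) -> list[PlantedPeak]:
        return [p for p in self.peaks if p.gene_id == gene_id]


def effective_gamma(peak: PlantedPeak, condition: str, genotype: str,
                    config: SimulationConfig) -> float:
    """Enrichment fold of a planted peak under a condition/genotype."""
    if genotype == "knockdown" and peak.dependent:
        return 1.0
    g = peak.gamma
    if condition == "HS" and peak.region == "utr5":
        g *= config.hs_utr5_factor
    return g


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

def make_annotation(config: SimulationConfig, seed: int):
    """Build a toy annotated genome with planted peaks.

    Returns (GenomeAnnotation, genome dict chrom -> sequence str, TruthSet).
    Genes carry 1-3 transcripts sharing a CDS core; a configurable fraction
    violates each model filter rule; modified genes carry one planted peak
    wholly inside its labeled region, with the consensus motif inserted in a
    configured fraction of peaks.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    truth = TruthSet()
    genome: dict[str, list[str]] = {}

    # assign filter violations up front
    viol_rules: list[str | None] = [None] * config.n_genes
    cursor = 0
    for rule in ("missing_utr", "utr5_short", "utr3_short", "cds_short"):
        n = int(round(config.violation_fractions.get(rule, 0.0) * config.n_genes))
        for _ in range(n):
            if cursor < config.n_genes:
                viol_rules[cursor] = rule
                cursor += 1
    order = rng.permutation(config.n_genes)
    viol_rules = [viol_rules[i] for i in order]

    n_mod = int(round(config.fraction_modified * config.n_genes))
    clean = [i for i in range(config.n_genes) if viol_rules[i] is None]
    mod_idx = set(int(i) for i in rng.choice(clean, size=min(n_mod, len(clean)),
                                             replace=False))

    pos: dict[str, int] = {}
    pending_peaks = []
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        chrom = f"chr{i // config.genes_per_chromosome + 1}"
        start = pos.get(chrom, 0) + config.intergenic_gap
        strand = "+" if rng.random() < 0.5 else "-"
        rule = viol_rules[i]

        u5 = int(rng.integers(*_rng_range(config.utr5_len)))
        cds = int(rng.integers(*_rng_range(config.cds_len)))
        u3 = int(rng.integers(*_rng_range(config.utr3_len)))
        if rule == "utr5_short":
            u5 = int(rng.integers(1, 30))
        elif rule == "utr3_short":
            u3 = int(rng.integers(1, 30))
        elif rule == "cds_short":
            cds = int(rng.integers(3, 100))
        has_cds = rule != "missing_utr"

        gene, spliced_len = _build_gene(rng, gid, chrom, strand, start,
                                        u5, cds, u3, has_cds, config)
        ann.genes[gid] = gene
        gene_end = max(e for t in gene.transcripts.values() for _, e in t.exons)
        pos[chrom] = gene_end
        truth.expression[gid] = float(rng.lognormal(0.0, config.expression_sigma))
        if rule is not None:
            truth.violations[gid] = rule
        truth.modified[gid] = i in mod_idx
        if i in mod_idx:
            pending_peaks.append((gid, u5, cds, u3))

    # genome sequences
    for chrom, end in sorted(pos.items()):
        n = end + config.intergenic_gap
        genome[chrom] = list(rng.choice(list("ACGT"), size=n))

    # plant peaks inside regions of the collapsed models
    models = collapse_annotation(ann)
    for gid, u5, cds, u3 in pending_peaks:
        model = models[gid]
        region_lens = {"utr5": u5, "cds": cds, "utr3": u3}
        w = np.asarray(config.region_weights, dtype=float).copy()
        regions = ("utr5", "cds", "utr3")
        peak = None
        for _ in range(20):
            region = regions[int(rng.choice(3, p=w / w.sum()))]
            lmax = min(config.peak_len[1], region_lens[region])
            if lmax < config.peak_len[0] and lmax < 50:
                continue
            plen = int(rng.integers(min(config.peak_len[0], lmax), lmax + 1))
            roff = int(rng.integers(0, region_lens[region] - plen + 1))
            peak = (region, plen, roff)
            break
        if peak is None:
            continue
        region, plen, roff = peak
        # transcript coordinate of the region start
        reg_off = {"utr5": 0, "cds": u5, "utr3": u5 + cds}[region]
        sp = (reg_off + roff, reg_off + roff + plen)
        smap = SplicedMap(model.exon_segments, model.strand)
        segs = smap.spliced_to_genomic(*sp)
        g0 = min(s for s, _ in segs)
        g1 = max(e for _, e in segs)
        dependent = bool(rng.random() < config.fraction_dependent)
        truth.peaks.append(PlantedPeak(gid, model.chrom, g0, g1, region, sp,
                                       config.gamma, dependent))
        if config.motif and rng.random() < config.motif_incidence:
            _plant_motif(rng, genome, model, smap, sp, config.motif)

    genome_str = {c: "".join(s) for c, s in genome.items()}
    return ann, genome_str, truth


def _rng_range(pair: tuple[int, int]) -> tuple[int, int]:
    return pair[0], pair[1] + 1


def _build_gene(rng, gid, chrom, strand, start, u5, cds, u3, has_cds, config):
    """Lay out a gene: spliced length u5+cds+u3, 1-3 exons, 1-3 transcripts."""
    spliced = u5 + cds + u3
    n_exons = int(rng.integers(1, config.max_exons + 1))
    n_exons = min(n_exons, max(1, spliced // 50))
    cut_pool = np.arange(1, spliced)
    cuts = np.sort(rng.choice(cut_pool, size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.empty(0, dtype=int)
    introns = [int(rng.integers(*_rng_range(config.intron_len)))
               for _ in range(n_exons - 1)]

    # exon genomic intervals, forward-spliced order
    exons = []
    g = start
    prev = 0
    for j, cut in enumerate(list(cuts) + [spliced]):
        exons.append((g, g + (cut - prev)))
        g += cut - prev
        if j < len(introns):
            g += introns[j]
        prev = cut
    smap_fwd_len = spliced

    # forward-spliced interval of the CDS depends on strand: transcript
    # coordinates run 5'->3', which is genomic order on + and reversed on -
    if has_cds:
        if strand == "+":
            cds_sp = (u5, u5 + cds)
        else:
            cds_sp = (u3, u3 + cds)   # forward-spliced coordinates
        cds_ivs = _spliced_to_genomic_fwd(exons, *cds_sp)
    else:
        cds_ivs = []

    gene = GeneRecord(gid, chrom, strand)
    gene.transcripts[f"{gid}.t1"] = Transcript(f"{gid}.t1", strand,
                                               list(exons), list(cds_ivs))
    n_tx = int(rng.integers(1, config.max_transcripts + 1))
    for k in range(2, n_tx + 1):
        # isoform sharing the CDS core with a truncated terminal UTR
        if not has_cds or len(exons) == 1:
            sub = list(exons)
        else:
            trim = int(rng.integers(0, max(1, min(u5, u3) // 2)))
            if strand == "+":
                lo = min(exons[0][0] + trim, cds_ivs[0][0])
                sub = _clip_exons(exons, lo, exons[-1][1])
            else:
                hi = max(exons[-1][1] - trim, cds_ivs[-1][1])
                sub = _clip_exons(exons, exons[0][0], hi)
        gene.transcripts[f"{gid}.t{k}"] = Transcript(f"{gid}.t{k}", strand,
                                                     sub, list(cds_ivs))
    return gene, smap_fwd_len


def _spliced_to_genomic_fwd(exons, a, b):
    out = []
    c = 0
    for s, e in exons:
        w = e - s
        lo = max(a, c)
        hi = min(b, c + w)
        if hi > lo:
            out.append((s + lo - c, s + hi - c))
        c += w
    return out


def _clip_exons(exons, lo, hi):
    return [(max(s, lo), min(e, hi)) for s, e in exons
            if min(e, hi) > max(s, lo)]


def _plant_motif(rng, genome, model, smap, sp, motif):
    """Insert the motif (transcript strand) at a random offset in the peak."""
    plen = sp[1] - sp[0]
    if plen < len(motif):
        return
    off = int(rng.integers(0, plen - len(motif) + 1))
    # on the minus strand the genomic sequence, read left to right, is the
    # reverse complement of the transcript motif
    segs = smap.spliced_to_genomic(sp[0] + off, sp[0] + off + len(motif))
    seq = motif if model.strand == "+" else reverse_complement(motif)
    i = 0
    for s, e in segs:
        for gpos in range(s, e):
            genome[model.chrom][gpos] = seq[i]
            i += 1


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_library(models: Mapping[str, GeneModel], truth: TruthSet,
                     config: SimulationConfig, seed: int, sample_type: str,
                     condition: str = "basal", genotype: str = "control",
                     sample_id: str | None = None) -> ReadSet:
    """Simulate one sequencing library as an in-memory :class:`ReadSet`.

    Input reads start uniformly over the spliced transcript; IP reads weight
    the start position so the read midpoint falls inside a planted peak with
    rate multiplied by that peak's effective gamma. Reads are spliced: a
    read crossing an intron carries one block per exon it touches.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    if sample_type not in ("IP", "input"):
        raise ValueError(f"sample_type must be IP or input, got {sample_type!r}")
    rng = np.random.default_rng(seed)
    rl = config.read_length
    per_chrom: dict[str, list] = {}
    rid_counter: dict[str, int] = {}
    total = 0
    for gid in sorted(models):
        model = models[gid]
        smap = SplicedMap(model.exon_segments, model.strand)
        L = smap.length
        if L < rl:
            continue
        n_starts = L - rl + 1
        weights = np.ones(n_starts, dtype=float)
        if sample_type == "IP":
            for peak in truth.peaks_of(gid):
                g = effective_gamma(peak, condition, genotype, config)
                lo = max(0, peak.spliced_interval[0] - rl // 2)
                hi = min(n_starts, peak.spliced_interval[1] - rl // 2)
                if hi > lo:
                    weights[lo:hi] *= g
        expr = truth.expression.get(gid, 1.0)
        mean_reads = config.depth * expr * weights.sum() / rl
        n = int(rng.poisson(mean_reads))
        if n == 0:
            continue
        cum = np.cumsum(weights)
        starts = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
        blocks = _reads_to_blocks(starts, rl, smap)
        base = rid_counter.get(model.chrom, 0)
        chrom_blocks = per_chrom.setdefault(model.chrom, [])
        for (s, e, local_rid) in blocks:
            chrom_blocks.append((s, e, base + local_rid))
        rid_counter[model.chrom] = base + n
        total += n
    sid = sample_id or f"{sample_type}_{condition}_{genotype}"
    rs = ReadSet(sid, {}, total)
    for chrom, blocks in per_chrom.items():
        rs.chroms[chrom] = _build_chrom(blocks, rid_counter[chrom])
    return rs


def _reads_to_blocks(starts: np.ndarray, rl: int, smap: SplicedMap):
    """Genomic (start, end, read_index) blocks for transcript-coord reads."""
    out = []
    for i, s in enumerate(starts):
        for gs, ge in smap.spliced_to_genomic(int(s), int(s) + rl):
            out.append((gs, ge, i))
    return out


def simulate_experiment(models: Mapping[str, GeneModel], truth: TruthSet,
                        config: SimulationConfig, seed: int,
                        conditions: Sequence[str] = CONDITIONS,
                        genotypes: Sequence[str] = GENOTYPES
                        ) -> dict[tuple[str, str, str, int], ReadSet]:
    """All libraries {IP, input} x condition x genotype x replicate.

    Keys are (sample_type, condition, genotype, replicate). Each library
    gets an independent, reproducible sub-seed.
    """
    libs = {}
    i = 0
    for condition in conditions:
        for genotype in genotypes:
            for rep in range(1, config.n_replicates + 1):
                for sample_type in ("IP", "input"):
                    sub = (seed * 100003 + i) % (2 ** 31 - 1)
                    libs[(sample_type, condition, genotype, rep)] = \
                        simulate_library(models, truth, config, sub,
                                         sample_type, condition, genotype,
                                         f"{sample_type}_{condition}_"
                                         f"{genotype}_r{rep}")
                    i += 1
    return libs


# ---------------------------------------------------------------------------
# DE tables and decay series
# ---------------------------------------------------------------------------

def simulate_de_table(truth: TruthSet, config: SimulationConfig, seed: int,
                      contrast: str = "HS_vs_basal") -> pd.DataFrame:
    """Differential-expression table with a planted up-skew for modified genes.

    Directed genes draw small adjusted p and a signed lognormal log2 fold
    change; null genes draw p_adj uniform on [0, 1] with a small centred
    fold change. The drawn direction is recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    directions = {}
    for gid in sorted(truth.modified):
        modified = truth.modified[gid]
        p_up = config.p_up_modified if modified else config.p_up_unmodified
        if rng.random() < config.p_directed:
            up = rng.random() < p_up
            lfc = float(rng.lognormal(0.0, config.lfc_sigma) * (1 if up else -1))
            p_adj = float(10.0 ** (-rng.uniform(1.4, 8.0)))
            directions[gid] = "up" if up else "down"
        else:
            lfc = float(rng.normal(0.0, 0.2))
            p_adj = float(rng.uniform(0.0, 1.0))
            directions[gid] = "ns"
        rows.append((gid, lfc, p_adj, True))
    truth.de_direction[contrast] = directions
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_adj", "expressed"])


def simulate_decay(truth: TruthSet, config: SimulationConfig, seed: int,
                   gene_ids: Sequence[str] | None = None,
                   timepoints: Sequence[float] = DECAY_TIMEPOINTS
                   ) -> pd.DataFrame:
    """Exponential decay series with lognormal noise per condition.

    Control transcripts decay with ``half_life_control``; knockdown with
    ``half_life_knockdown`` (methylation loss stabilizes targets).
    """
    if config.half_life_control <= 0 or config.half_life_knockdown <= 0:
        raise ValueError("half-lives must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids) if gene_ids is not None else \
        sorted(g for g, m in truth.modified.items() if m)
    hl = {"control": config.half_life_control,
          "knockdown": config.half_life_knockdown}
    sigma = np.sqrt(np.log(1 + config.decay_noise_cv ** 2))
    rows = []
    for gid in gene_ids:
        truth.half_life[gid] = dict(hl)
        for cond, h in hl.items():
            k = np.log(2) / h
            for rep in range(1, config.decay_replicates + 1):
                for t in timepoints:
                    noise = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
                    rows.append((gid, cond, rep, t, float(np.exp(-k * t) * noise)))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate",
                                       "time_h", "level"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path: str | os.PathLike,
                       width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(reads: ReadSet, genome_lengths: Mapping[str, int],
              path: str | os.PathLike) -> None:
    """Write a ReadSet as coordinate-sorted SAM with spliced (N) CIGARs."""
    chroms = sorted(genome_lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(genome_lengths[c])} for c in chroms]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for chrom in chroms:
            creads = reads.chroms.get(chrom)
            if creads is None:
                continue
            grouped: dict[int, list[tuple[int, int]]] = {}
            for s, e, r in zip(creads.block_start, creads.block_end,
                               creads.read_id):
                grouped.setdefault(int(r), []).append((int(s), int(e)))
            recs = []
            for r, blocks in grouped.items():
                blocks.sort()
                recs.append((blocks[0][0], r, blocks))
            recs.sort()
            tid = chroms.index(chrom)
            for start, r, blocks in recs:
                a = pysam.AlignedSegment()
                a.query_name = f"{reads.sample_id}.{chrom}.{r}"
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 60
                a.flag = 0
                cigar = []
                prev_end = None
                for s, e in blocks:
                    if prev_end is not None and s > prev_end:
                        cigar.append((3, s - prev_end))      # N
                    cigar.append((0, e - s))                 # M
                    prev_end = e
                a.cigartuples = cigar
                out.write(a)


def write_truth(truth: TruthSet, path: str | os.PathLike) -> None:
    payload = {
        "modified": truth.modified,
        "expression": truth.expression,
        "violations": truth.violations,
        "de_direction": truth.de_direction,
        "half_life": truth.half_life,
        "peaks": [asdict(p) for p in truth.peaks],
    }
    def _coerce(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_coerce)


def load_config(path: str | os.PathLike) -> SimulationConfig:
    with open(path) as fh:
        raw = json.load(fh)
    cfg = SimulationConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        default = getattr(cfg, key)
        if isinstance(default, tuple):
            value = tuple(value)
        cfg = replace(cfg, **{key: value})
    return cfg.validate()
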