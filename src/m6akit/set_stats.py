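"""Gene-set statistics and motif background construction.

Covers the downstream statistics of a MeRIP-seq study: classification of
differential-expression tables, one-sided Fisher tests for expression skew
of a gene class, one-sided hypergeometric tests for set overlaps,
length-matched background sequence sampling from expressed peak-free
transcript regions, and a k-mer Fisher-enrichment surrogate for de novo
motif finding (lengths 5-7).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_models import GeneModel, SplicedMap, intersect_intervals
from .peaks import Peak, PeakSet

DE_COLUMNS = ("gene_id", "log2fc", "p_adj")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SetTestResult:
    test: str                            # fisher_one_sided | hypergeometric_one_sided
    table: tuple[tuple[int, int], tuple[int, int]] | None
    statistic: float                     # odds ratio or observed overlap
    expected: float
    p: float
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# DE classification and skew
# ---------------------------------------------------------------------------

def load_de_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_de_table(table)


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table lacks required columns: {missing}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in DE table: {dups[:5]}")
    bad = table[(table["p_adj"] < 0) | (table["p_adj"] > 1)]
    if len(bad):
        raise ValueError("adjusted p values outside [0, 1]")
    if "expressed" not in table.columns:
        table = table.assign(expressed=True)
    return table


def classify_de(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Label genes up / down / ns at adjusted p < alpha.

    A significant gene with log2fc == 0 carries no direction and is ns.
    """
    table = validate_de_table(table)
    sig = table["p_adj"] < alpha
    label = np.where(sig & (table["log2fc"] > 0), "up",
                     np.where(sig & (table["log2fc"] < 0), "down", "ns"))
    return pd.Series(label, index=table["gene_id"].to_numpy(), name="label")


def skew_test(labels: pd.Series, in_class: Mapping[str, bool] | set,
              mode: str = "within_significant") -> SetTestResult:
    """One-sided Fisher test for over-representation of up-regulation in a class.

    Default table (``within_significant``): rows class / non-class, columns
    up / down among significant genes. The alternative ``up_vs_rest`` tests
    up against everything else over the whole universe.
    """
    if isinstance(in_class, set) or isinstance(in_class, frozenset):
        member = {g: (g in in_class) for g in labels.index}
    else:
        member = dict(in_class)
    idx = [g for g in labels.index if g in member]
    lab = labels.loc[idx]
    mem = np.array([member[g] for g in idx])
    if mode == "within_significant":
        keep = lab.isin(["up", "down"]).to_numpy()
        lab, mem = lab[keep], mem[keep]
        up = (lab == "up").to_numpy()
    elif mode == "up_vs_rest":
        up = (lab == "up").to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    a = int(np.sum(mem & up))
    b = int(np.sum(mem & ~up))
    c = int(np.sum(~mem & up))
    d = int(np.sum(~mem & ~up))
    table = ((a, b), (c, d))
    for name, margin in (("class", a + b), ("non-class", c + d),
                         ("up", a + c), ("not-up", b + d)):
        if margin == 0:
            raise ValueError(f"empty margin in skew test: no {name} genes")
    odds, p = stats.fisher_exact(table, alternative="greater")
    n = a + b + c + d
    expected = (a + b) * (a + c) / n
    return SetTestResult("fisher_one_sided", table, float(odds), expected,
                         float(p), {"mode": mode})


def overlap_test(set_a: Iterable[str], set_b: Iterable[str],
                 universe: Iterable[str]) -> SetTestResult:
    """One-sided hypergeometric test of the overlap of two gene sets.

    p = P(X >= |A n B|), X ~ Hypergeometric(|U|, |A|, |B|).
    """
    uni = set(universe)
    a = set(set_a)
    b = set(set_b)
    off_a = sorted(a - uni)
    off_b = sorted(b - uni)
    if off_a or off_b:
        raise ValueError(f"sets not contained in universe; offenders: "
                         f"{(off_a + off_b)[:10]}")
    k = len(a & b)
    M, nA, nB = len(uni), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    expected = nA * nB / M if M else 0.0
    return SetTestResult("hypergeometric_one_sided", None, float(k), expected,
                         min(p, 1.0), {"universe": M, "n_a": nA, "n_b": nB})


# ---------------------------------------------------------------------------
# motif background
# ---------------------------------------------------------------------------

def spliced_sequence(model: GeneModel, genome: Mapping[str, str],
                     segments: Sequence[tuple[int, int]] | None = None) -> str:
    """Exon-concatenated sequence in transcript orientation."""
    segs = segments if segments is not None else model.exon_segments
    chrom_seq = genome[model.chrom]
    seq = "".join(str(chrom_seq[s:e]) for s, e in segs)
    return reverse_complement(seq) if model.strand == "-" else seq


def peak_sequence(peak: Peak, model: GeneModel, genome: Mapping[str, str]) -> str:
    segs = intersect_intervals(model.exon_segments, [(peak.start, peak.end)])
    if not segs:
        segs = [(peak.start, peak.end)]
    return spliced_sequence(model, genome, segs)


def background_sequences(peaks: PeakSet, expressed_models: Mapping[str, GeneModel],
                         genome: Mapping[str, str], seed: int,
                         buffer: int = 0, max_tries: int = 2000):
    """Length-matched background from expressed, peak-free transcript regions.

    For each peak one interval of identical (exonic) length is drawn
    uniformly from the exonic spans of the expressed models, rejection
    sampling away any interval whose genomic footprint comes within
    ``buffer`` bp of any input peak. Deterministic under ``seed``.

    Returns (peak_seqs, background_seqs, background_intervals) where each
    background interval is (gene_id, chrom, genomic segments, strand).
    """
    if not expressed_models:
        raise ValueError("no expressed models to sample background from")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(expressed_models)
    maps = {g: SplicedMap(expressed_models[g].exon_segments,
                          expressed_models[g].strand) for g in gene_ids}
    lengths = np.array([maps[g].length for g in gene_ids], dtype=float)

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(
            (p.start - buffer, p.end + buffer))

    peak_seqs = []
    for p in sorted(peaks, key=lambda q: (q.chrom, q.start, q.end, q.gene_id)):
        model = expressed_models.get(p.gene_id)
        if model is not None:
            peak_seqs.append(peak_sequence(p, model, genome))
        else:
            peak_seqs.append(str(genome[p.chrom][p.start:p.end]))

    bg_seqs = []
    bg_intervals = []
    for seq in peak_seqs:
        L = len(seq)
        ok_genes = np.flatnonzero(lengths >= L)
        if len(ok_genes) == 0:
            raise ValueError(f"no expressed transcript long enough for a "
                             f"{L} bp background interval")
        weights = (lengths[ok_genes] - L + 1)
        weights = weights / weights.sum()
        for _ in range(max_tries):
            g = gene_ids[int(rng.choice(ok_genes, p=weights))]
            model = expressed_models[g]
            smap = maps[g]
            start = int(rng.integers(0, smap.length - L + 1))
            segs = smap.spliced_to_genomic(start, start + L)
            clash = any(s < pe and e > ps
                        for s, e in segs
                        for ps, pe in by_chrom.get(model.chrom, ()))
            if not clash:
                bg_seqs.append(spliced_sequence(model, genome, segs))
                bg_intervals.append((g, model.chrom, segs, model.strand))
                break
        else:
            raise ValueError(f"could not place a peak-free background interval "
                             f"of length {L} in {max_tries} tries")
    return peak_seqs, bg_seqs, bg_intervals


def write_fasta(seqs: Sequence[str], path: str | os.PathLike,
                prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, 1):
            fh.write(f">{prefix}{i}\n{s}\n")


def read_fasta(path: str | os.PathLike) -> list[str]:
    seqs: list[str] = []
    with open(path) as fh:
        cur: list[str] = []
        for line in fh:
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            else:
                cur.append(line.strip())
        if cur:
            seqs.append("".join(cur))
    return seqs


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def kmer_enrichment(peak_seqs: Sequence[str], background_seqs: Sequence[str],
                    k_range: Iterable[int] = (5, 6, 7), alpha: float = 0.05,
                    rna: bool = True) -> pd.DataFrame:
    """Presence/absence k-mer Fisher enrichment of peak vs background sequences.

    For every k-mer observed in either set a 2x2 table of sequences
    containing it (peak vs background) is tested one-sided for enrichment in
    peaks; BH correction runs across all k-mers of all lengths. Ranked by
    adjusted then raw p. ``rna=True`` displays k-mers in the RNA alphabet.
    """
    if not peak_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")
    peak_norm = [_normalize_seq(s) for s in peak_seqs]
    bg_norm = [_normalize_seq(s) for s in background_seqs]
    rows = []
    for k in k_range:
        peak_sets = [_kmer_set(s, k) for s in peak_norm]
        bg_sets = [_kmer_set(s, k) for s in bg_norm]
        all_kmers = sorted(set().union(*peak_sets, *bg_sets))
        for kmer in all_kmers:
            a = sum(kmer in s for s in peak_sets)
            c = sum(kmer in s for s in bg_sets)
            b = len(peak_sets) - a
            d = len(bg_sets) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((kmer, k, a, c, float(odds), float(p)))
    df = pd.DataFrame(rows, columns=["kmer", "k", "n_peak", "n_background",
                                     "odds_ratio", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["significant"] = df["p_adj"] < alpha
    df = df.sort_values(["p_adj", "p", "kmer"], kind="stable").reset_index(drop=True)
    if rna:
        df["kmer"] = df["kmer"].str.replace("T", "U")
    return df


def _normalize_seq(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return s


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k]}


# ---------------------------------------------------------------------------
# gene-set I/O
# ---------------------------------------------------------------------------

def read_gene_set(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
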