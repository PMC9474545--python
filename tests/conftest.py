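"""Shared fixtures: hand-built gene models and read sets for oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from m6akit.coverage_metagene import ReadSet, _build_chrom
from m6akit.gene_models import GeneModel, GeneRecord, Transcript


def make_model(gene_id="g1", chrom="chr1", strand="+",
               exons=((0, 300),), utr5=((0, 100),), cds=((100, 200),),
               utr3=((200, 300),)) -> GeneModel:
    return GeneModel(gene_id, chrom, strand, [tuple(iv) for iv in exons],
                     {"utr5": [tuple(iv) for iv in utr5],
                      "cds": [tuple(iv) for iv in cds],
                      "utr3": [tuple(iv) for iv in utr3]})


def make_readset(blocks_by_read, chrom="chr1", sample_id="test",
                 extra_reads=0) -> ReadSet:
    """blocks_by_read: list of block lists, one entry per read.

    ``extra_reads`` inflates the library size without adding alignments on
    the modeled chromosome (reads mapped elsewhere).
    """
    flat = []
    for rid, blocks in enumerate(blocks_by_read):
        for s, e in blocks:
            flat.append((s, e, rid))
    rs = ReadSet(sample_id, {}, len(blocks_by_read) + extra_reads)
    if flat:
        rs.chroms[chrom] = _build_chrom(flat, len(blocks_by_read))
    return rs


def random_gene_record(rng, gene_id="g1", chrom="chr1", strand=None,
                       n_transcripts=None) -> GeneRecord:
    """A random multi-transcript gene for collapse oracles."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_transcripts = n_transcripts or int(rng.integers(1, 4))
    origin = int(rng.integers(0, 500))
    gene = GeneRecord(gene_id, chrom, strand)
    for t in range(n_transcripts):
        n_exons = int(rng.integers(1, 4))
        pos = origin + int(rng.integers(0, 50))
        exons = []
        for _ in range(n_exons):
            width = int(rng.integers(30, 200))
            exons.append((pos, pos + width))
            pos += width + int(rng.integers(20, 100))
        span = (exons[0][0], exons[-1][1])
        has_cds = rng.random() < 0.9
        cds = []
        if has_cds:
            lo = int(rng.integers(span[0], span[1] - 1))
            hi = int(rng.integers(lo + 1, span[1] + 1))
            for s, e in exons:
                s2, e2 = max(s, lo), min(e, hi)
                if e2 > s2:
                    cds.append((s2, e2))
        gene.transcripts[f"{gene_id}.t{t}"] = Transcript(
            f"{gene_id}.t{t}", strand, exons, cds)
    return gene


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
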