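"""End-to-end desk-scale MeRIP-seq analysis on a synthetic experiment.

Runs the full chain — annotation, gene-model collapse and filtering, read
simulation, bin counting, enrichment, peak calling, region assignment,
differential methylation, gene-set statistics, motif background/k-mer
enrichment and decay fitting — writing every result as deterministic TSV /
BED / FASTA text into an output directory.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import pandas as pd

from . import coverage_metagene as cm
from . import decay_qpcr as dq
from . import peaks as pk
from . import set_stats as ss
from . import synthetic_data as syn
from .gene_models import (collapse_annotation, filter_models,
                          write_filter_report_tsv, write_gtf, write_models_tsv)


def run_pipeline(config: syn.SimulationConfig, seed: int, outdir: str,
                 pseudocount: float = cm.DEFAULT_PSEUDOCOUNT) -> dict:
    """Simulate one experiment and analyse it; returns a summary dict."""
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"seed": seed}

    ann, genome, truth = syn.make_annotation(config, seed)
    write_gtf(ann, os.path.join(outdir, "annotation.gtf"))
    syn.write_genome_fasta(genome, os.path.join(outdir, "genome.fa"))
    syn.write_truth(truth, os.path.join(outdir, "truth.json"))

    models = collapse_annotation(ann)
    report = filter_models(models.values())
    write_models_tsv([models[g] for g in sorted(models)],
                     os.path.join(outdir, "gene_models.tsv"))
    write_filter_report_tsv(report, os.path.join(outdir, "filter_report.tsv"))
    kept = {g: models[g] for g in report.kept}
    grids = {g: cm.make_grid(kept[g]) for g in kept}
    summary["n_genes"] = len(models)
    summary["n_kept"] = len(kept)

    libs = syn.simulate_experiment(models, truth, config, seed)

    # metagene enrichment per condition (control genotype)
    profiles = {}
    for condition in syn.CONDITIONS:
        ip = [cm.count_matrix(libs[("IP", condition, "control", r)], kept, grids)
              for r in range(1, config.n_replicates + 1)]
        inp = [cm.count_matrix(libs[("input", condition, "control", r)], kept,
                               grids)
               for r in range(1, config.n_replicates + 1)]
        enr = cm.enrichment(ip, inp, pseudocount, condition=condition)
        cm.write_matrix_tsv(enr, os.path.join(outdir,
                                              f"enrichment_{condition}.tsv"))
        profile, n = cm.metagene_profile(enr)
        cm.write_profile_tsv(profile, n,
                             os.path.join(outdir, f"profile_{condition}.tsv"))
        profiles[condition] = (enr, profile)
        z, _ = cm.zscore_rows(enr.values)
        pd.DataFrame(z, index=enr.genes, columns=cm.bin_labels()).to_csv(
            os.path.join(outdir, f"heatmap_z_{condition}.tsv"), sep="\t",
            float_format="%.6g")
    summary["profile_argmax_bin_basal"] = int(np.nanargmax(profiles["basal"][1]))

    t = cm.paired_region_test(
        cm.region_mean(profiles["HS"][0], "utr5"),
        cm.region_mean(profiles["basal"][0], "utr5"))
    summary["utr5_paired_t"] = {"t": t.statistic, "df": t.df, "p": t.pvalue}

    # peak calling on pooled basal control libraries
    ip_pool = cm.merge_readsets(
        [libs[("IP", "basal", "control", r)]
         for r in range(1, config.n_replicates + 1)], "IP_basal_control")
    in_pool = cm.merge_readsets(
        [libs[("input", "basal", "control", r)]
         for r in range(1, config.n_replicates + 1)], "input_basal_control")
    peakset = pk.call_peaks(ip_pool, in_pool, kept, pseudocount=pseudocount)
    pk.assign_all(peakset, kept)
    pk.write_peaks_bed(peakset, os.path.join(outdir, "peaks.bed"))
    if len(peakset):
        dist = pk.region_distribution(peakset)
        summary["peak_region_distribution"] = dist
    summary["n_peaks"] = len(peakset)

    # Mettl3 dependence: control vs knockdown at basal
    control = [(libs[("IP", "basal", "control", r)],
                libs[("input", "basal", "control", r)])
               for r in range(1, config.n_replicates + 1)]
    knockdown = [(libs[("IP", "basal", "knockdown", r)],
                  libs[("input", "basal", "knockdown", r)])
                 for r in range(1, config.n_replicates + 1)]
    results = pk.differential_methylation(control, knockdown, kept,
                                          pseudocount=pseudocount)
    pk.write_diffmeth_tsv(results, os.path.join(outdir, "diffmeth.tsv"))
    m6a_genes = pk.m6a_gene_set(results)
    ss.write_gene_set(m6a_genes, os.path.join(outdir, "m6a_genes.txt"))
    summary["n_m6a_genes"] = len(m6a_genes)

    # DE skew and overlap statistics
    de = syn.simulate_de_table(truth, config, seed + 7, "HS_vs_basal")
    de.to_csv(os.path.join(outdir, "de_HS_vs_basal.tsv"), sep="\t",
              index=False, float_format="%.6g")
    labels = ss.classify_de(de)
    universe = list(de["gene_id"])
    m6a_in_universe = [g for g in m6a_genes if g in set(universe)]
    stats_rows = []
    if m6a_in_universe:
        skew = ss.skew_test(labels, set(m6a_in_universe))
        stats_rows.append(("skew_m6a_up_HS", "fisher_one_sided", skew.p,
                           json.dumps(skew.table)))
        summary["skew_p"] = skew.p
        up = [g for g in universe if labels.loc[g] == "up"]
        ov = ss.overlap_test(m6a_in_universe, up, universe)
        stats_rows.append(("overlap_m6a_up_HS", "hypergeometric_one_sided",
                           ov.p, json.dumps({"overlap": ov.statistic,
                                             "expected": ov.expected})))
        summary["overlap_p"] = ov.p
    pd.DataFrame(stats_rows, columns=["name", "test", "p", "detail"]).to_csv(
        os.path.join(outdir, "set_stats.tsv"), sep="\t", index=False,
        float_format="%.6g")

    # motif background + k-mer enrichment
    if len(peakset):
        try:
            pseq, bseq, _ = ss.background_sequences(peakset, kept, genome,
                                                    seed + 11)
            ss.write_fasta(pseq, os.path.join(outdir, "peaks.fa"), "peak")
            ss.write_fasta(bseq, os.path.join(outdir, "background.fa"), "bg")
            kmers = ss.kmer_enrichment(pseq, bseq)
            kmers.head(100).to_csv(os.path.join(outdir, "kmer_enrichment.tsv"),
                                   sep="\t", index=False, float_format="%.6g")
            summary["top_kmer"] = str(kmers.iloc[0]["kmer"]) if len(kmers) else None
        except ValueError:
            summary["top_kmer"] = None

    # decay
    series = syn.simulate_decay(truth, config, seed + 13)
    series.to_csv(os.path.join(outdir, "decay_series.tsv"), sep="\t",
                  index=False, float_format="%.6g")
    fits = dq.fit_decay_table(series)
    fits.to_csv(os.path.join(outdir, "decay_fits.tsv"), sep="\t", index=False,
                float_format="%.6g")
    if len(fits):
        med = fits.groupby("condition")["half_life_h"].median()
        summary["median_half_life_h"] = {c: float(v) for c, v in med.items()}

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
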