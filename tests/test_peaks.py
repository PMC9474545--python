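"""Peak calling, majority-rule assignment and dependence calling."""

import math

import numpy as np
import pytest

from m6akit.coverage_metagene import merge_readsets
from m6akit.gene_models import collapse_annotation, filter_models
from m6akit.peaks import (Peak, PeakSet, assign_peak_region, call_peaks,
                          differential_methylation, m6a_gene_set,
                          region_distribution, write_peaks_bed)
from m6akit.synthetic_data import (SimulationConfig, make_annotation,
                                   simulate_library)

from conftest import make_model, make_readset


def _sim_models_reads(seed, n_genes=60, gamma=8.0, genotype="control",
                      n_rep=3, cfg=None):
    cfg = cfg or SimulationConfig(n_genes=n_genes, gamma=gamma)
    ann, _, truth = make_annotation(cfg, seed)
    models = collapse_annotation(ann)
    kept = {g: models[g] for g in filter_models(models.values()).kept}
    ip = merge_readsets([simulate_library(models, truth, cfg, seed * 991 + i,
                                          "IP", "basal", genotype)
                         for i in range(n_rep)])
    inp = merge_readsets([simulate_library(models, truth, cfg,
                                           seed * 991 + 500 + i, "input",
                                           "basal", genotype)
                          for i in range(n_rep)])
    return cfg, truth, kept, ip, inp


class TestCallPeaks:
    def test_strong_window_is_significant(self):
        """100 IP vs 10 input reads in one window, equal library sizes."""
        model = make_model(exons=((0, 1000),), utr5=((0, 200),),
                          cds=((200, 800),), utr3=((800, 1000),))
        ip = make_readset([[(0, 50)]] * 100 + [[(500, 550)]] * 100,
                          sample_id="ip")
        inp = make_readset([[(0, 50)]] * 10 + [[(500, 550)]] * 190,
                           sample_id="in")
        peaks = call_peaks(ip, inp, {"g1": model})
        assert any(p.start < 50 and p.end > 0 for p in peaks)
        hit = next(p for p in peaks if p.start < 50)
        # pooled cpm ratio ~= 10 with equal library sizes
        assert hit.enrichment == pytest.approx(10.0, rel=0.1)

    def test_equal_libraries_give_no_peaks(self):
        model = make_model(exons=((0, 1000),), utr5=((0, 200),),
                          cds=((200, 800),), utr3=((800, 1000),))
        reads = make_readset([[(i % 900, i % 900 + 100)] for i in range(500)])
        assert len(call_peaks(reads, reads, {"g1": model})) == 0

    def test_null_simulation_yields_no_peaks(self):
        cfg = SimulationConfig(n_genes=60, gamma=1.0, hs_utr5_factor=1.0)
        _, _, kept, ip, inp = _sim_models_reads(9, cfg=cfg)
        assert len(call_peaks(ip, inp, kept)) <= 1

    def test_planted_peaks_recovered(self):
        _, truth, kept, ip, inp = _sim_models_reads(5)
        peaks = call_peaks(ip, inp, kept)
        planted = [p for p in truth.peaks if p.gene_id in kept]
        hits = sum(1 for tp in planted
                   if any(q.gene_id == tp.gene_id and q.start < tp.end
                          and q.end > tp.start for q in peaks))
        assert hits / len(planted) >= 0.9

    def test_sensitivity_monotone_in_gamma(self):
        sens = []
        for gamma in (2.0, 4.0, 8.0):
            _, truth, kept, ip, inp = _sim_models_reads(5, gamma=gamma)
            peaks = call_peaks(ip, inp, kept)
            planted = [p for p in truth.peaks if p.gene_id in kept]
            hits = sum(1 for tp in planted
                       if any(q.gene_id == tp.gene_id and q.start < tp.end
                              and q.end > tp.start for q in peaks))
            sens.append(hits / len(planted))
        assert sens == sorted(sens)

    def test_deterministic_bed_output(self, tmp_path):
        _, _, kept, ip, inp = _sim_models_reads(6, n_genes=30)
        out = []
        for i in range(2):
            peaks = call_peaks(ip, inp, kept)
            path = tmp_path / f"peaks{i}.bed"
            write_peaks_bed(peaks, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_zero_input_library_raises(self):
        model = make_model()
        ip = make_readset([[(0, 10)]])
        with pytest.raises(ValueError, match="input"):
            call_peaks(ip, make_readset([]), {"g1": model})


class TestAssignRegion:
    def test_contained_in_utr5(self):
        peak = Peak("chr1", 10, 60, "g1", 1.0, 5.0)
        assert assign_peak_region(peak, make_model()) == "utr5"

    def test_majority_wins(self):
        """40 bp in CDS, 60 bp in 3'UTR -> utr3."""
        peak = Peak("chr1", 160, 260, "g1", 1.0, 5.0)
        assert assign_peak_region(peak, make_model()) == "utr3"

    def test_tie_broken_by_priority(self):
        peak = Peak("chr1", 50, 150, "g1", 1.0, 5.0)  # 50 utr5 + 50 cds
        assert assign_peak_region(peak, make_model()) == "utr5"
        peak2 = Peak("chr1", 150, 250, "g1", 1.0, 5.0)  # 50 cds + 50 utr3
        assert assign_peak_region(peak2, make_model()) == "cds"

    def test_no_exonic_overlap_unassigned(self):
        model = make_model(exons=((0, 100), (300, 500)), utr5=((0, 100),),
                           cds=((300, 450),), utr3=((450, 500),))
        peak = Peak("chr1", 150, 250, "g1", 1.0, 5.0)
        with pytest.warns(UserWarning, match="unassigned"):
            assert assign_peak_region(peak, model) == "unassigned"

    def test_agrees_with_per_base_brute_force(self, rng):
        """Majority rule matches exhaustive per-base labeling, 1,000 pairs."""
        from conftest import random_gene_record
        from m6akit.gene_models import collapse_gene
        priority = ("utr5", "cds", "utr3")
        checked = 0
        while checked < 1000:
            model = collapse_gene(random_gene_record(rng, f"g{checked}"))
            if not model.coding:
                continue
            span = model.span
            s = int(rng.integers(span[0] - 20, span[1]))
            e = s + int(rng.integers(10, 200))
            labels = {r: 0 for r in priority}
            for pos in range(max(s, span[0]), min(e, span[1])):
                for r in priority:
                    if any(a <= pos < b for a, b in model.region_segments[r]):
                        labels[r] += 1
            if sum(labels.values()) == 0:
                continue
            best = max(labels.values())
            expected = next(r for r in priority if labels[r] == best)
            peak = Peak(model.chrom, s, e, model.gene_id, 1.0, 1.0)
            assert assign_peak_region(peak, model) == expected
            checked += 1


class TestRegionDistribution:
    def _peakset(self, counts):
        peaks = []
        i = 0
        for region, n in counts.items():
            for _ in range(n):
                p = Peak("chr1", i * 10, i * 10 + 5, f"g{i}", 1.0, 2.0, region)
                peaks.append(p)
                i += 1
        return PeakSet(peaks)

    def test_percentages(self):
        dist = region_distribution(self._peakset({"utr5": 94, "cds": 4,
                                                  "utr3": 2}))
        assert dist["utr5"]["percent"] == pytest.approx(94.0)
        assert dist["cds"]["percent"] == pytest.approx(4.0)
        assert dist["utr3"]["percent"] == pytest.approx(2.0)

    def test_single_peak(self):
        dist = region_distribution(self._peakset({"cds": 1}))
        assert dist["cds"]["percent"] == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="assigned"):
            region_distribution(PeakSet([]))

    def test_planted_labels_recovered(self):
        _, truth, kept, ip, inp = _sim_models_reads(5)
        from m6akit.peaks import assign_all
        peaks = assign_all(call_peaks(ip, inp, kept), kept)
        planted = {p.gene_id: p.region for p in truth.peaks}
        for q in peaks:
            tp = planted.get(q.gene_id)
            if tp is not None:
                assert q.assigned_region == tp


class TestDifferentialMethylation:
    def _paired_readsets(self, n_ip, n_in, reps=2, lib_pad=200):
        """Replicate pairs with a fixed count over one 50-bp bin."""
        pairs = []
        for r in range(reps):
            ip = make_readset([[(0, 50)]] * n_ip, extra_reads=lib_pad - n_ip,
                              sample_id=f"ip{r}")
            inp = make_readset([[(0, 50)]] * n_in, extra_reads=lib_pad - n_in,
                               sample_id=f"in{r}")
            pairs.append((ip, inp))
        return pairs

    def test_identical_conditions_no_calls(self):
        model = make_model(exons=((0, 50),), utr5=((0, 10),), cds=((10, 40),),
                           utr3=((40, 50),))
        pairs = self._paired_readsets(20, 20)
        res = differential_methylation(pairs, pairs, {"g1": model})
        assert all(r.beta == 0 for r in res if r.passes_count_filter)
        assert not m6a_gene_set(res)

    def test_count_filter_excludes_low_bins(self):
        """Summed IP of 14 in one condition blocks the bin outright."""
        model = make_model(exons=((0, 50),), utr5=((0, 10),), cds=((10, 40),),
                           utr3=((40, 50),))
        control = self._paired_readsets(50, 20)
        treatment = self._paired_readsets(7, 20)   # 7+7 = 14 < 15
        res = differential_methylation(control, treatment, {"g1": model})
        assert len(res) == 1
        assert not res[0].passes_count_filter
        assert not res[0].dependent

    def test_needs_two_replicates(self):
        model = make_model()
        pairs = self._paired_readsets(20, 20, reps=1)
        with pytest.raises(ValueError, match="replicates"):
            differential_methylation(pairs, pairs, {"g1": model})

    def test_knockdown_recovery(self):
        cfg = SimulationConfig(n_genes=50)
        ann, _, truth = make_annotation(cfg, 8)
        models = collapse_annotation(ann)
        kept = {g: models[g] for g in filter_models(models.values()).kept}
        ctrl = [(simulate_library(models, truth, cfg, 8000 + i, "IP"),
                 simulate_library(models, truth, cfg, 8100 + i, "input"))
                for i in range(3)]
        kd = [(simulate_library(models, truth, cfg, 8200 + i, "IP", "basal",
                                "knockdown"),
               simulate_library(models, truth, cfg, 8300 + i, "input", "basal",
                                "knockdown"))
              for i in range(3)]
        res = differential_methylation(ctrl, kd, kept)
        called = set(m6a_gene_set(res))
        truth_genes = {p.gene_id for p in truth.peaks
                       if p.dependent and p.gene_id in kept}
        inter = len(called & truth_genes)
        union = len(called | truth_genes)
        assert inter / union >= 0.8   # Jaccard against planted truth

    def test_permuted_label_null_calls_rare(self):
        """Relabeled control replicates produce (almost) no dependent bins."""
        cfg = SimulationConfig(n_genes=25)
        ann, _, truth = make_annotation(cfg, 12)
        models = collapse_annotation(ann)
        kept = {g: models[g] for g in filter_models(models.values()).kept}
        pairs = [(simulate_library(models, truth, cfg, 12000 + i, "IP"),
                  simulate_library(models, truth, cfg, 12100 + i, "input"))
                 for i in range(6)]
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(10):
            idx = rng.permutation(6)
            res = differential_methylation([pairs[i] for i in idx[:3]],
                                           [pairs[i] for i in idx[3:]], kept)
            tested = [r for r in res if r.passes_count_filter]
            rates.append(sum(r.dependent for r in tested) / len(tested))
        assert np.mean(rates) <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / len(rates))


class TestGeneSet:
    def test_empty_and_dedup(self):
        from m6akit.peaks import DiffMethylResult
        mk = lambda g, dep: DiffMethylResult(g, 0, "chr1", 0, 50, -2.0, 1e-4,
                                             1e-3, True, dep)
        assert m6a_gene_set([mk("a", False)]) == []
        assert m6a_gene_set([mk("a", True), mk("a", True)]) == ["a"]
        assert m6a_gene_set([mk("b", True), mk("a", True)]) == ["a", "b"]
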