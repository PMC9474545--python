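"""Bin grids, overlap counting, normalization, profiles and tracks."""

import math

import numpy as np
import pytest

from m6akit.coverage_metagene import (BinCoverageMatrix, count_bin_reads,
                                      enrichment, log_ratio_track, make_grid,
                                      metagene_profile, normalize_bins,
                                      normalize_values, paired_region_test,
                                      zscore_rows)
from m6akit.gene_models import SplicedMap, collapse_annotation, filter_models
from m6akit.synthetic_data import (SimulationConfig, make_annotation,
                                   simulate_library)

from conftest import make_model, make_readset


def model_with_lengths(u5, cds, u3, gene_id="g1", strand="+"):
    L = u5 + cds + u3
    return make_model(gene_id, strand=strand, exons=((0, L),),
                      utr5=((0, u5),), cds=((u5, u5 + cds),),
                      utr3=((u5 + cds, L),))


class TestGrid:
    def test_divisible_region(self):
        grid = make_grid(model_with_lengths(300, 1000, 300))
        assert np.all(grid.widths[:30] == 10)

    def test_remainder_goes_to_first_bins(self):
        grid = make_grid(model_with_lengths(31, 100, 60))
        assert list(grid.widths[:30]) == [2] + [1] * 29
        assert list(grid.widths[30:130]) == [1] * 100

    def test_too_short_region_raises(self):
        with pytest.raises(ValueError, match="cannot be tiled"):
            make_grid(model_with_lengths(29, 100, 60))

    def test_bins_cover_regions_exactly(self):
        grid = make_grid(model_with_lengths(77, 513, 41))
        assert grid.boundaries[0] == 0
        assert grid.boundaries[30] == 77
        assert grid.boundaries[130] == 77 + 513
        assert grid.boundaries[-1] == 77 + 513 + 41


def brute_force_counts(reads_blocks, model, grid):
    """Independent oracle: per-read, per-bin genomic interval intersection."""
    smap = grid.splice_map
    bin_segments = [smap.spliced_to_genomic(int(a), int(b))
                    for a, b in zip(grid.boundaries[:-1], grid.boundaries[1:])]
    counts = np.zeros(grid.n_bins, dtype=int)
    for blocks in reads_blocks:
        for i, segs in enumerate(bin_segments):
            hit = any(min(be, e) > max(bs, s)
                      for bs, be in blocks for s, e in segs)
            counts[i] += hit
    return counts


class TestCounting:
    def test_read_inside_one_bin(self):
        model = model_with_lengths(300, 1000, 300)
        grid = make_grid(model)
        reads = make_readset([[(10, 20)]])
        counts = count_bin_reads(reads, model, grid)
        assert counts[1] == 1 and counts.sum() == 1

    def test_read_spanning_three_bins(self):
        model = model_with_lengths(300, 1000, 300)
        grid = make_grid(model)
        reads = make_readset([[(0, 30)]])
        counts = count_bin_reads(reads, model, grid)
        assert list(counts[:3]) == [1, 1, 1] and counts.sum() == 3

    def test_intronic_read_counts_nowhere(self):
        model = make_model(exons=((0, 100), (200, 400)), utr5=((0, 60),),
                           cds=((60, 100), (200, 360)), utr3=((360, 400),))
        grid = make_grid(model)
        assert count_bin_reads(make_readset([[(120, 180)]]), model, grid).sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        """1,000 random reads over random models equal the intersection oracle."""
        for trial in range(8):
            u5 = int(rng.integers(40, 200))
            cds = int(rng.integers(150, 600))
            u3 = int(rng.integers(40, 200))
            strand = "+" if trial % 2 else "-"
            intron_at = u5 + cds // 2
            L = u5 + cds + u3
            intron = 150

            # genomic region segments around a single intron
            def shift(iv):
                s, e = iv
                out = []
                if s < intron_at:
                    out.append((s, min(e, intron_at)))
                if e > intron_at:
                    out.append((max(s, intron_at) + intron, e + intron))
                return out
            fwd = {"utr5": (0, u5), "cds": (u5, u5 + cds), "utr3": (u5 + cds, L)}
            regions = {k: shift(v) for k, v in fwd.items()}
            if strand == "-":
                regions = {"utr5": regions["utr3"], "cds": regions["cds"],
                           "utr3": regions["utr5"]}
            model = make_model(strand=strand,
                               exons=((0, intron_at), (intron_at + intron,
                                                       L + intron)),
                               **regions)
            grid = make_grid(model)
            blocks_per_read = []
            span = L + intron
            for _ in range(125):
                kind = rng.random()
                if kind < 0.6:   # plain genomic interval, may cross the intron
                    s = int(rng.integers(-20, span))
                    w = int(rng.integers(1, 120))
                    blocks_per_read.append([(s, s + w)])
                elif kind < 0.85:  # spliced two-block read
                    s = int(rng.integers(0, max(1, intron_at - 40)))
                    blocks_per_read.append(
                        [(s, s + 30), (intron_at + intron,
                                       intron_at + intron + 30)])
                else:             # gapped read (deletion-like spliced gap)
                    s = int(rng.integers(0, span - 100))
                    blocks_per_read.append([(s, s + 20), (s + 60, s + 90)])
            reads = make_readset(blocks_per_read)
            got = count_bin_reads(reads, model, grid)
            want = brute_force_counts(blocks_per_read, model, grid)
            np.testing.assert_array_equal(got, want)


class TestNormalization:
    def test_formula(self):
        assert normalize_values(np.array([10]), np.array([10]), 10 ** 6) == \
            pytest.approx(1.0)
        assert normalize_values(np.array([0]), np.array([7]), 100)[0] == 0.0

    def test_zero_library_raises(self):
        with pytest.raises(ValueError, match="library"):
            normalize_values(np.array([1]), np.array([1]), 0)

    def test_scale_invariance(self, rng):
        counts = rng.integers(0, 50, size=(5, 160))
        widths = rng.integers(1, 20, size=(5, 160))
        a = normalize_values(counts, widths, 10_000)
        b = normalize_values(counts * 2, widths, 20_000)
        np.testing.assert_allclose(a, b)

    def test_flat_coverage_gives_equal_bins(self, rng):
        """Uniform per-base coverage: all 160 normalized values equal."""
        for trial in range(50):
            u5 = int(rng.integers(31, 120))
            cds = int(rng.integers(101, 700))
            u3 = int(rng.integers(31, 120))
            model = model_with_lengths(u5, cds, u3,
                                       strand="+" if trial % 2 else "-")
            grid = make_grid(model)
            L = u5 + cds + u3
            reads = make_readset([[(p, p + 1)] for p in range(L)])
            counts = count_bin_reads(reads, model, grid)
            values = normalize_bins(counts, grid, reads.n_reads)
            assert np.all(counts == grid.widths)
            np.testing.assert_allclose(values, values[0], rtol=1e-9)


class TestEnrichment:
    def _matrix(self, counts, widths, lib, sample="s"):
        counts = np.asarray(counts)
        return BinCoverageMatrix(sample, ["g1"], counts.reshape(1, -1),
                                 np.asarray(widths).reshape(1, -1), lib)

    def test_single_replicate_ratio(self):
        ip = self._matrix([20], [10], 10 ** 6)
        inp = self._matrix([10], [10], 10 ** 6)
        enr = enrichment([ip], [inp], pseudocount=0.0)
        assert enr.values[0, 0] == pytest.approx(2.0)

    def test_replicate_sum_invariance(self):
        ip = self._matrix([20], [10], 10 ** 6)
        inp = self._matrix([10], [10], 10 ** 6)
        one = enrichment([ip], [inp], pseudocount=0.0)
        two = enrichment([ip, ip], [inp, inp], pseudocount=0.0)
        np.testing.assert_allclose(one.values, two.values)

    def test_matches_brute_force(self, rng):
        """Sum counts, sum libraries, apply the formula bin by bin."""
        widths = rng.integers(1, 15, size=160)
        ip = [self._matrix(rng.integers(0, 40, 160), widths,
                           int(rng.integers(10 ** 4, 10 ** 5)))
              for _ in range(3)]
        inp = [self._matrix(rng.integers(0, 40, 160), widths,
                            int(rng.integers(10 ** 4, 10 ** 5)))
               for _ in range(2)]
        pc = 0.25
        got = enrichment(ip, inp, pc).values[0]
        ip_sum = sum(m.raw_counts[0] for m in ip)
        in_sum = sum(m.raw_counts[0] for m in inp)
        ip_lib = sum(m.library_size for m in ip)
        in_lib = sum(m.library_size for m in inp)
        want = ((ip_sum / widths / ip_lib * 1e6 + pc)
                / (in_sum / widths / in_lib * 1e6 + pc))
        np.testing.assert_allclose(got, want)

    def test_mismatched_genes_raise(self):
        a = self._matrix([1], [1], 100)
        b = BinCoverageMatrix("s", ["g2"], np.array([[1]]), np.array([[1]]), 100)
        with pytest.raises(ValueError, match="g2"):
            enrichment([a], [b])


class TestProfileAndZscore:
    def test_single_gene_profile_is_row(self, rng):
        m = BinCoverageMatrix("s", ["g1"], rng.integers(0, 9, (1, 160)),
                              np.ones((1, 160), dtype=int), 1000)
        profile, n = metagene_profile(m)
        np.testing.assert_allclose(profile, m.values[0])
        assert np.all(n == 1)

    def test_constant_matrix_is_flat(self):
        m = BinCoverageMatrix("s", ["a", "b"], np.full((2, 160), 7),
                              np.ones((2, 160), dtype=int), 1000)
        profile, _ = metagene_profile(m)
        np.testing.assert_allclose(profile, profile[0])

    def test_planted_utr5_signal_peaks_in_utr5_bins(self):
        cfg = SimulationConfig(n_genes=200, region_weights=(1.0, 0.0, 0.0))
        ann, _, truth = make_annotation(cfg, 17)
        models = collapse_annotation(ann)
        kept = {g: models[g] for g in filter_models(models.values()).kept}
        grids = {g: make_grid(m) for g, m in kept.items()}
        from m6akit.coverage_metagene import count_matrix
        ip = count_matrix(simulate_library(models, truth, cfg, 171, "IP"),
                          kept, grids)
        inp = count_matrix(simulate_library(models, truth, cfg, 172, "input"),
                           kept, grids)
        profile, _ = metagene_profile(enrichment([ip], [inp]))
        assert int(np.nanargmax(profile)) < 30

    def test_zscore_definition(self):
        z, flags = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.0, 0.0, 1.0]])
        assert not flags[0]

    def test_constant_row_flagged_zero(self):
        z, flags = zscore_rows(np.array([[5.0, 5.0, 5.0]]))
        assert np.all(z == 0) and flags[0]

    def test_random_rows_standardized(self, rng):
        z, flags = zscore_rows(rng.normal(size=(20, 160)))
        assert not flags.any()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, rtol=1e-12)


class TestTrack:
    def test_equal_coverage_is_zero(self):
        cov = np.full(50, 8.0)
        track = log_ratio_track(cov, cov, 1000, 1000, pseudocount=0.0)
        np.testing.assert_allclose(track, 0.0)

    def test_fourfold_is_two(self):
        track = log_ratio_track(np.full(10, 4.0), np.full(10, 1.0),
                                1000, 1000, pseudocount=0.0)
        np.testing.assert_allclose(track, 2.0)

    def test_matches_per_base_brute_force(self, rng):
        ip = rng.integers(0, 30, 200).astype(float)
        inp = rng.integers(0, 30, 200).astype(float)
        pc = 0.25
        got = log_ratio_track(ip, inp, 5000, 8000, pc)
        want = [math.log2((a / 5000 * 1e6 + pc) / (b / 8000 * 1e6 + pc))
                for a, b in zip(ip, inp)]
        np.testing.assert_allclose(got, want)

    def test_span_mismatch_raises(self):
        with pytest.raises(ValueError, match="span"):
            log_ratio_track(np.ones(5), np.ones(6), 1, 1)


class TestPairedTest:
    def test_identical_vectors(self):
        res = paired_region_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.df == 2

    def test_matches_hand_formula(self):
        b = np.zeros(3)
        a = np.array([1.1, 0.9, 1.0])
        res = paired_region_test(a, b)
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert res.statistic == pytest.approx(expected_t)
        assert res.df == 2

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError, match="n >= 3"):
            paired_region_test([1.0, 2.0], [0.0, 1.0])

    def test_type_one_error_calibrated(self, rng):
        """Under no shift the paired test rejects at ~alpha."""
        n_runs, n = 1000, 12
        rejections = 0
        for _ in range(n_runs):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            if paired_region_test(a, b).pvalue < 0.05:
                rejections += 1
        rate = rejections / n_runs
        mc = 2 * math.sqrt(0.05 * 0.95 / n_runs)
        assert rate <= 0.05 + mc


def test_spliced_map_round_trip(rng):
    segments = [(0, 100), (250, 400), (500, 520)]
    for strand in "+-":
        smap = SplicedMap(segments, strand)
        for _ in range(50):
            a = int(rng.integers(0, smap.length))
            b = int(rng.integers(a + 1, smap.length + 1))
            segs = smap.spliced_to_genomic(a, b)
            assert sum(e - s for s, e in segs) == b - a
            back = smap.genomic_to_spliced(min(s for s, _ in segs),
                                           max(e for _, e in segs))
            assert back == (a, b)
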