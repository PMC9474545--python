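# Methods

This note documents the statistical model and design choices behind
`m6akit`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Gene models

Transcript isoforms of a gene are collapsed into one model per gene by
taking the interval union of all exons. Regions are derived from the
*outermost CDS boundaries* over all transcripts: every exonic base between
the outermost CDS start and end is CDS; exonic bases 5' of that span in
transcript orientation are 5'UTR, those 3' of it 3'UTR. This rule is
deterministic for any annotation dialect, guarantees that
|5'UTR| + |CDS| + |3'UTR| equals the total exonic length of a coding gene,
and matches the union behavior one gets from reducing per-transcript
ranges. Conflicting isoform annotations (a CDS overlapping another
isoform's UTR) are therefore resolved in favor of the CDS. Genes without
any annotated CDS are flagged non-coding.

Inclusion filters for metagene analysis: both UTRs present, each UTR
≥ 30 bp, CDS ≥ 100 bp. Exclusion reasons are assigned in the fixed order
`missing_utr, utr5_short, utr3_short, cds_short` (first failing check), so
reports are reproducible. Non-coding genes fail `missing_utr`.

Coordinates are 0-based half-open internally; GTF/GFF3 input (1-based
inclusive) is converted on read and BED/bedGraph output is written 0-based
half-open. Trans-spliced and multi-chromosome genes are unsupported.

## Metagene binning and normalization

Each kept gene is tiled with 30 + 100 + 30 bins over 5'UTR/CDS/3'UTR in
transcript orientation. When a region length is not divisible by the bin
count, the remainder is distributed deterministically to the most-5' bins
(widths differ by at most 1 bp). A read increments every bin whose genomic
footprint it overlaps by at least one exonic base — overlap counting, not
fractional apportionment — and a read spanning k bins counts in all k.
Counting is per aligned read; paired mates would count independently.
Spliced alignments contribute all blocks; intronic-only reads count
nowhere. Internally, counting exploits the fact that the exonic image of
any genomic interval is contiguous in spliced coordinates, reducing bin
lookup to rank queries.

Normalization is `count / bin_width_bp / library_size × 1e6` (reads per
million per bp), which makes uniform per-base coverage exactly flat across
the 160 bins despite unequal widths. Replicates of one condition are
combined by summing raw counts and library sizes *before* the IP/input
ratio is taken (not by averaging per-replicate ratios). A pseudocount
(default 0.25) is added to both numerator and denominator of every ratio;
it only matters in near-zero-coverage bins.

Known artifact: per-gene IP/input ratios are unstable in the last (and
first) bins of a transcript, where read-start geometry tapers coverage in
both libraries toward zero; with few genes a single zero-input bin can
visibly bump the mean profile. At the benchmark scale (≥200 genes) the
planted 5'UTR signal dominates — the profile argmax landed in the 5'UTR
bins in 20/20 seeded datasets — but mean profiles over very small gene sets
should be read with this in mind.

Row z-scores for heatmaps use the sample standard deviation (n−1); constant
rows cannot be scaled and are emitted as zeros with a flag. Genome-browser
tracks are per-base log2((IP_cpm + pc)/(input_cpm + pc)) written as
bedGraph. The paired comparison of per-gene region enrichment between two
conditions is a standard paired two-tailed t-test; identical vectors return
t = 0, p = 1 by convention.

## Peak calling (surrogate)

HMM-based MeRIP peak callers are not reimplemented. The surrogate slides
50-bp windows (step 25) along the spliced exonic sequence of each gene and
tests the IP read count x against n = x + y (y the input count) with a
one-sided binomial test at the null proportion p0 = N_IP/(N_IP + N_input)
given by the library sizes. BH correction runs across all windows of all
genes. A window enters a peak only if its adjusted p < 0.05 **and** its
library-normalized IP/input ratio is ≥ 2 — the fold floor is standard
practice in enrichment peak calling and is what keeps the spurious-peak
rate low: at 30× pooled coverage, ~1.5-fold fluctuations reach formal
significance, and window-level BH alone does not control the peak-level
false discovery proportion. Maximal runs of qualifying windows are merged;
each peak reports its genomic span, pooled enrichment over its spliced
extent and −log10 of the run's minimum adjusted p. Identical inputs give
byte-identical BED output.

Peaks are assigned to the region holding the largest share of their exonic
footprint (majority rule); exact ties go to 5'UTR > CDS > 3'UTR, a fixed,
configurable priority chosen to mirror the 5'UTR-dominant biology.

## Differential methylation (surrogate)

Mettl3 dependence is tested per exonic 50-bp bin. The replicate-level
methylation level is m = log2((IP_cpm + pc)/(input_cpm + pc)); beta is the
mean difference (treatment − control). Bins whose summed raw IP count is
below 15 in either condition are excluded before testing. A bin is called
*dependent* when adjusted p < 0.05, |beta| ≥ 0.5 and beta ≤ −1 — i.e. at
least a two-fold log2 loss from control to knockdown; the fold-change
threshold is interpreted on the log2 scale and is configurable. The m6A
gene set is the genes with ≥ 1 dependent bin.

With 2–3 replicates per condition a plain Welch t-test has ~2–4 degrees of
freedom; its attainable p-values (≥ ~1e-4) cannot survive BH correction
across thousands of bins even for 8-fold losses. The default test is
therefore an empirical-Bayes **moderated t**: per-bin pooled variances are
shrunk toward a scaled inverse-chi-square prior whose scale and prior df
are fitted by moments on the log variances across all tested bins, and the
moderated statistic has d + d0 degrees of freedom. This is the standard
remedy for small-replicate designs; replicate variability still enters the
statistic. The plain Welch test remains available (`variance="welch"`).
Under permuted-label nulls the dependent-call rate stays below alpha, and
the directional beta ≤ −1 requirement makes null calls rare.

## Gene-set statistics

DE tables (gene, log2 fold change, BH-adjusted p) are classified up/down/ns
at adjusted p < 0.05; a significant gene with log2FC exactly 0 carries no
direction and is ns. The skew test builds the 2×2 table class × direction
among significant genes and returns the one-sided Fisher p for
over-representation of "up" in the class; an alternative construction
(up vs rest of the whole universe) is available behind a flag. The overlap
test is the one-sided hypergeometric tail P(X ≥ observed overlap) with the
universe defaulting to all expressed genes. Both tests were verified
against exact factorial enumeration (Fractions) to 1e-10 relative error on
enumerated and random tables.

Motif analysis is a k-mer surrogate: for each k in 5–7, each k-mer observed
in either set is tested for presence/absence (not occurrence counts, which
keeps the 2×2 exact) in peak vs background sequences with a one-sided
Fisher test, BH corrected across all k-mers. Background sequences are
length-matched to the peaks and drawn uniformly from the exonic spans of
expressed genes, rejection-sampling away anything overlapping a peak
(flanking buffer default 0 bp, configurable); sampling is deterministic
under the seed. Sequences are handled in the DNA alphabet and displayed as
RNA.

## Decay and qPCR

ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control), fold = 2^−ΔΔCt; invariant to any constant shift applied
to all Ct values. No amplification-efficiency correction is applied.

Decay series (levels relative to the no-drug control, timepoints 0, 0.5, 1,
2, 4 h) are fit with N(t) = N0·e^(−kt) by linear least squares on log
levels — deterministic and closed-form, adequate for 4–5 timepoints; the
intercept is free by default and can be pinned to N0 = 1. A fitted k ≤ 0 is
returned with a no-decay flag and infinite half-life. The reported RSS is
of the fitted curve against the levels on the linear scale. Fraction
remaining at 4 h is e^(−4k) in fit mode or level(4 h)/level(0) in raw mode;
group comparisons use the Student pooled-variance two-tailed t-test with
the same zero-variance conventions as above.

## Synthetic experiment

The generator's defaults are the emulated study conditions: 3 biological
replicates per genotype and condition; ~30× mean per-base input coverage
with 100-bp spliced single-end reads; 14.1% of expressed genes modified;
planted peak placement weighted (0.9, 0.07, 0.03) over (5'UTR, CDS,
3'UTR); enrichment fold γ = 8 inside planted peaks, multiplied by 1.5 in
5'UTRs under heat shock and reset to 1 in the knockdown for dependent
peaks; DE up-probabilities 0.8 (modified) vs 0.4 (unmodified) among
directed genes; decay half-lives 1 h (control) vs 4 h (knockdown) with 10%
lognormal noise and 6 replicates. Gene lengths are uniform on 60–600 bp
(UTRs) and 300–3000 bp (CDS); genes carry 1–3 transcripts sharing a CDS
core, 1–3 exons, one chromosome per 25 genes. A GGACU consensus motif is
inserted into 60% of planted peaks. Everything is reproducible from an
integer seed, and byte-identical across runs.

IP read-start positions are weighted so that a read's midpoint falls inside
a planted peak with rate multiplied by γ; input starts are uniform over the
spliced transcript. The generator does **not** model sequencing errors,
quality scores, fragment-size distributions, alignment ambiguity, PCR
duplicates, or 5'/3' coverage bias beyond the geometric edge taper — so
passing recovery benchmarks demonstrates the correctness and calibration of
the statistics under idealized Poisson sampling, not robustness to the
technical noise of real libraries.

## Benchmark problem sizes

The recovery benchmarks run at deliberately desk-scale sizes chosen to give
stable proportions: peak recovery on one 200-gene dataset (3 pooled
replicates per library, ~28 planted peaks) plus a 200-gene null;
differential methylation on twenty 50-gene datasets (3 vs 3 replicates) and
fifty label permutations of six control replicates; skew calibration on
1,000 null simulations and 40 power simulations at n = 2,000 genes; exact
test oracles on all 2×2 tables of total ≤ 12–16 plus hundreds of random
tables with margins ≤ 30; decay recovery on 100 noisy fits. Headline
numbers from the original full-scale data (e.g. the exact percentage of
5'UTR peaks, or specific gene counts) are *not* reproduction targets: they
depend on real libraries and the internals of MetPeak/RADAR/DESeq2, which
are intentionally out of scope.

## Known limitations

- Peak boundaries are window-quantized (25 bp) and bleed ~half a read
  length beyond the true planted interval; recovery is scored by overlap,
  not boundary accuracy.
- The moderated-t dependence test assumes approximately normal bin-level
  log-ratios; at very low counts the pseudocount dominates and bins are
  (by design) removed by the count filter instead.
- The surrogate peak caller tests windows independently and does not model
  spatial autocorrelation beyond run-merging.
- Background sampling excludes peak overlap but not compositional matching
  (GC content) of the background to the peaks.
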