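# Methods

## Score tracks and binning

Two per-base (or per-window) score tracks are consumed as 4-column bedGraph:
an intra-species constraint score (CDTS-like; lower values mean stronger
depletion of variation, i.e. more constrained) and a cross-species
conservation probability (phastCons-like, in [0, 1]). Both are summarised
into non-overlapping fixed-width bins — 10 bp by default, matching the
resolution at which such constraint maps are published — by a
coverage-weighted mean over the bases each interval covers. Bins with zero
covered bases are missing. Where a bin is only partially covered (e.g. a
conservation track with alignment gaps), the mean is taken over the covered
bases only; the alternative (treating uncovered bases as zero) would
conflate "unknown" with "unconserved". Chromosomes whose length is not a
multiple of the bin width get one truncated terminal bin that remains
eligible for scoring, so no territory is silently dropped.

All coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted on read, and a gene's span is the union over all of
its transcripts — the natural multi-transcript reading of "transcription
start and stop sites". Strand is ignored for all track operations (the
scores are strandless) and retained only on gene models.

Joining the two binned tracks keeps only bins carrying both scores and
reports counts and fractions dropped per reason. An optional blacklist
(ENCODE-style problematic regions) can flag or drop bins overlapping it by
at least 1 bp; by default it is used for accounting only.

## CNC score and annotation categories

Both binned scores are ranked jointly across all chromosomes so that the
highest rank marks the most constrained (lowest constraint score) and most
conserved bin respectively. Ties receive midranks (average ranks): the CNC
score is a log ratio of ranks, so ranks must be well defined and
reproducible under ties; ordinal ranking would make the score depend on row
order. The CNC score of a bin is `log2(rank_constraint /
rank_conservation)`; it is antisymmetric under swapping the two ranks,
strictly increasing in the constraint rank, and its distribution is centred
at 0 when the two rankings carry no joint information.

Three categories are called:

* **constrained** — the `floor(0.125 N)` bins with the highest constraint
  rank. Rank ties straddling the cutoff are broken positionally (chromosome
  order, then start), so exactly k bins are selected and repeat runs are
  identical.
* **CNCR** — constrained bins with CNC ≥ 1 (inclusive threshold). Adjacent
  qualifying bins are merged; bins separated by an unscored gap are not.
* **non-conserved** — bins whose conservation rank is at or below a
  threshold, irrespective of constraint. The GRCh38 value published for the
  real tracks (25,623,592) is accepted verbatim as an override. The
  "derive" mode recomputes it from the data as the genome-wide conservation
  midrank of the first-quartile conservation score among bins with
  |CNC − 1| ≤ tol (tol = 0.01 by default). The published derivation sentence
  is ambiguous about which bin set the quartile is taken over; this
  implementation fixes one documented reading and exposes the threshold as a
  parameter rather than claiming to reproduce the published rank.

The constrained bins are partitioned into ten equally sized deciles by CNC
score (sizes differing by at most one; ties broken positionally), with the
"90-100" decile holding the highest scores. Compositions across deciles are
computed by assigning each bin a single feature from an ordered priority
hierarchy (coding-first by default, fully overridable via YAML; the ≥1 bp
overlap rule is used since no minimum is established for this assignment).
Fold enrichments between extreme deciles are ratios of row-normalised
proportions, with folds below 1 reported as x-fold depletions and zero
denominators flagged as infinite rather than dropped. The 2×2 test is the
chi-squared with Yates' continuity correction, with the corrected deviation
floored at 0 (the standard convention that avoids negative corrected
deviations); `scipy.stats.chi2_contingency` is used as an independent
cross-check in the tests, not as the implementation.

## Gene-level metrics

CNCR density of a gene is `overlap_bp / span_bp` against the merged CNCR
interval set, counting the whole gene span (introns included) rather than
exonic territory. Gene sets are thresholded on a density grid (> 0.0, then
≥ 0.1 … ≥ 0.5); the first cutoff is strict so that the "any CNCR at all"
set excludes zero-density genes, and the sets are nested by construction.
The biotype trend is an unweighted OLS slope of each biotype's proportion
(among genes passing each cutoff) on the numeric cutoff, with
Benjamini–Hochberg FDR across biotypes; cutoffs with empty gene sets are
dropped and at least three non-empty cutoffs are required. Distribution
comparisons between gene lists use the two-sided Wilcoxon rank-sum test
(exact for small tie-free samples, normal approximation with continuity
correction otherwise), reporting medians and IQRs.

LDSC export writes the thin-annot dialect: one binary column per category,
aligned to a supplied SNP table (1-based positions converted to 0-based for
the half-open membership test). Running stratified LDSC itself is out of
scope.

## Intron-retention usage

For a designated target intron of a reference exon chain, per sample:

* `cov_fraction` = mean per-base coverage over the intron ÷ mean per-base
  coverage over the gene span. Means (not sums) are used on both sides so
  the fraction is independent of interval lengths; the source description
  does not state mean vs sum, and the mean is the length-free choice.
* `junc_fraction` = reads on the junction that splices the intron out ÷
  reads over all annotated junctions of the gene. Junctions absent from the
  annotated set are counted and logged but excluded from the denominator.
* `ratio = cov_fraction / junc_fraction` — higher means more usage of the
  intron-retaining transcript. The ratio is exactly invariant under uniform
  scaling of depth, so no library-size normalisation (e.g. scaling to a
  target read count) is applied. A zero junction fraction yields an
  infinite ratio; such samples, and samples with zero gene coverage or zero
  annotated junction reads, are excluded listwise from downstream models
  with a logged reason.

The separate cross-species quantity is (total intron coverage ÷ intron
length) ÷ total gene coverage, keeping the explicit length-and-total
normalisation needed when intron lengths differ between species.

Group contrasts use the tie-corrected Kruskal–Wallis omnibus test plus all
pairwise two-sided rank-sum tests with BH adjustment. Ordinal predictors
(ε4 dosage 0/1/2, treated as numeric; Braak or CERAD stage) are modelled by
OLS of the ratio on the predictor plus covariates; categorical covariates
are one-hot encoded against an explicit reference level, and a
rank-deficient design raises an error naming the collinear columns. Braak
stages are merged I/II → mild, III/IV → moderate, V/VI → severe.
Leave-one-group-out refits the model excluding each batch in turn as a
robustness check against outlying batches.

## Synthetic data generator

The generator emulates the *shape* of the study's inputs at desk scale:

* **Genome and genes.** A few chromosomes of 600 kb each (1.8 Mb total,
  180,000 10-bp bins by default) with ~200 non-overlapping genes drawn from
  a biotype mixture (50% protein-coding, 22% lncRNA, plus miRNA, snRNA and
  pseudogenes), multi-exon for the long biotypes, written as GTF.
* **Score tracks.** Background constraint is 2× a standard normal;
  background conservation is the normal CDF of a variate correlated at 0.5
  with (minus) the constraint variate, so constrained bins tend to be
  conserved, as in real genomes — the annotation is designed to exploit
  departures from exactly that correlation. 16% of background bins lack a
  constraint score and 0.218% lack a conservation score (the coverage gaps
  of the real maps); planted bins are always scored. Planted CNCR blocks
  (60 × 600 bp) receive constraint drawn from background quantiles 0.001 to
  0.04 and conservation from quantiles 0.02 to 0.20; control blocks receive
  the same extreme constraint but conservation above quantile 0.96, so a
  correct caller recovers every planted base and never calls a control.
* **Planted gene structure.** 70% of blocks are genic. lncRNA hosts are
  planted densely (multiple blocks targeting ~0.45 density); hosts of other
  biotypes get a single block and must span at least five block lengths, so
  one block leaves their density moderate. This produces the biotype
  gradient the gene-level analyses are asserted against (protein-coding
  share falling, lncRNA share rising with the density cutoff). Tiny
  single-exon RNA genes are excluded as hosts — one block would saturate
  them and swamp the gradient with high-variance densities. A designated
  25-gene "neuro" list receives 70% of the genic blocks, giving it the
  elevated median density the list comparison is asserted against.
  Enhancer intervals cover every planted block (plus random background
  enhancers), supplying the regulatory-enrichment pattern across deciles.
* **IR cohort.** A six-exon gene (1,000 bp of exon, 2,900 bp span, five
  annotated junctions) with intron 3 (600 bp) as the target. Each of 600
  samples draws an ε4 dosage under Hardy–Weinberg (allele frequency 0.2), a
  batch, a Braak stage and demographic covariates; its target usage ratio
  is baseline 0.3 + 0.1 × dosage + 0.04 × (Braak − 1) + batch shift +
  N(0, 0.05) noise. The planted dosage effect is parametrised **on the
  usage-ratio scale** — the scale on which the model's slope is estimated —
  and the matching retention fraction ρ is obtained by inverting the
  deterministic measurement map (a ratio of quadratics in ρ; the inversion
  solves the quadratic and takes the root in (0, 1)). Parametrising the
  effect on ρ instead would make the recoverable slope depend nonlinearly
  on the gene geometry. Counting noise is Poisson on per-region coverage
  totals and on junction reads (dispersion 1, pure counting noise), with
  the target junction rate proportional to 1 − ρ and a small novel
  (unannotated) junction to exercise the annotation filter. Truths —
  planted intervals, per-gene expected density, per-sample ρ and target
  ratio, model coefficients — are serialised with every fixture bundle, and
  all randomness flows from one master seed through per-generator streams
  keyed by stable labels, so adding a generator does not shift the others
  and regeneration is byte-identical.

What the generator does *not* emulate: real sequence content, read-level
noise, correlated missingness (real constraint-map gaps cluster in
problematic regions), alignment artefacts, isoform complexity beyond one
alternative transcript, or pre-mRNA background coverage over non-target
introns. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted effects under idealised noise,
not performance on real tracks.

## Numerical choices and problem sizes

Ranks are exact integers or half-integers (midranks) in double precision;
interval sets are merged half-open integer intervals. The test suite runs
the full pipeline at the default 180,000-bin scale (seconds), checks the
12.5% selection fraction on one million bins, the null median CNC on one
million independently permuted rank pairs (|median| ≤ 0.02), dosage-slope
recovery at n = 600 (±0.02 around the planted 0.1), slope unbiasedness as a
mean over 100 cohorts of n = 150 (within 10%), and type-I error over 400
null cohorts of n = 150 (rejection rate in [0.03, 0.07] at nominal 0.05);
400 cohorts keep the binomial width of the empirical rate well inside that
band. Brute-force oracles (per-base overlap counting, sort-and-scan
selection and merging) back the interval operations on fixtures up to
10,000 bins.

## Known limitations

* The derived non-conserved rank threshold implements one documented
  reading of an ambiguous derivation; on real tracks the published rank
  should be supplied explicitly.
* The feature priority order ships with a sensible coding-first default but
  is a configuration choice, not a reproduction of any specific published
  ordering.
* The measured usage ratio is a slightly biased estimator of the target
  ratio at low junction counts (Jensen effect of the ratio of Poisson
  counts); at the default depths the bias is ~1–2%, within the asserted
  tolerances.
* bigWig is not parsed natively; export to bedGraph first. Liftover,
  GO-term enrichment, OMIM/STOPGAP retrieval and running stratified LDSC
  are out of scope.
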