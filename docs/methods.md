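# Methods

This note documents the models, parameter choices and numerical decisions
behind `clonetrack`, and what the synthetic-data generators do and do not
emulate.

## Barcode extraction and error collapsing

Reads carry a 31-bp insert (27-bp barcode + 4-bp library ID) between
constant flanks; three staggered primer pairs were used for amplification,
so extraction accepts any of the three flank variants. Filters apply in
order: flank match, exact 31-bp length, A/C/G/T alphabet, minimum insert
base quality ≥ Q30. Every read is accounted for — extracted counts plus
per-reason rejections equal the input reads at every stage.

Because the length filter precedes grouping, all retained inserts have
equal length and edit distance coincides with Hamming distance; collapsing
therefore uses Hamming distance ≤ 1. The collapse is a greedy
centroid absorption in descending read count (ties lexicographic), the
directional scheme used for UMI deduplication: deterministic,
read-conserving and idempotent. Tests check exact agreement with an
exhaustive nearest-centroid oracle.

The published barcode design is "semi-random" with an unprinted template;
the generator draws barcodes uniformly over {A,C,G,T}²⁷. Uniform libraries
have collision properties at least as adverse as a constrained design with
fixed positions removed, so the diversity bound measured on them is
conservative. A configurable pattern hook exists for users who know their
template. The 4-bp library ID's position within the insert is also
unprinted; it defaults to the final four bases and is configurable.

## Spike-in calibration

Calibration regresses log₁₀(known cells) on log₁₀(FRV) by ordinary least
squares — in that direction, not the reverse, because the estimation target
is cells. Spike-ins with zero reads cannot enter a log-log fit; they are
excluded and reported. The read threshold for "possibly aberrant" barcodes
is unspecified upstream; it is exposed as `min_reads` (useful values remove
the single-read tail produced by double sequencing errors, which can
otherwise pass the limit of detection at low depth).

## Doubling-time mixture

The mixture fit is a hand-written univariate Gaussian EM: k-means++-style
seeded initial means, ten restarts (short runs, the best continued to
convergence), σ floored at 10⁻⁶, relative log-likelihood tolerance 10⁻¹⁰.
K is selected by AIC over 1..max_K (BIC by flag) with 3K−1 parameters per
model. The per-iteration log-likelihood trajectory is exposed and tested
for monotonicity, and the fit is cross-checked against scikit-learn's EM
on the same data. Speed classes are assigned by maximum posterior
(default); hard density-crossing cutoffs between adjacent components are
also computed and available, since either reading is consistent with
published cutoff-line figures. Degenerate (zero-variance) samples return a
flagged K=1 fit rather than an error.

## Growth model parameterization

The growth model states both a rate parameter of 1/μ for the exponential
daily increments and that the per-day mean of log₂(N_t) is the rate's
reciprocal; combined with doubling time = t/log₂(N_t) these cannot all
hold. The package parameterizes so that the *realized* doubling time
concentrates at the configured μ: increments rᵢ have mean 1/μ doublings
per day (Exp rate = μ). This makes the simulator self-consistent with the
statistic it must reproduce. The literal reading (Exp rate = 1/μ) is
available via `literal_rate=True`. The time step is one day; the increment
that crosses a cap is kept. The 10⁷-cell capacity is applied at the
population level by default ("total cells"), with a per-clone option.

## Detection simulator

Founders double synchronously to the target cell number (equal clone sizes
up to rounding) because this simulation isolates the sampling artifact;
growth-rate variation belongs to the growth simulator. Reads are drawn
multinomially over cells with replacement, standing in for PCR
amplification; 50 repetitions per sample by default. Slope correction
subtracts the simulated log–log slope from the experimental one with
standard errors propagated in quadrature. Note the simulated dose–response
is not exactly linear in log–log space (detection saturates at low dose),
so slope standard errors from few dose levels are wide.

## Single-cell layer

* Multi-barcode patterns seen in exactly one cell are doublets
  (blacklisted); patterns repeated across ≥2 cells are multiple
  integrations, resolved to the barcode with the highest aggregate read
  count (lexicographic tie-break — the upstream rule does not name which
  barcode is kept).
* The metacell graph is the undirected union of each node's top-3
  neighbours (mutuality unspecified upstream); ties break by node id.
  Distances are breadth-first from the nearest root (metacells with ≥3
  primary-passage cells of the clone), tested exactly against brute-force
  shortest paths.
* Module enrichment over distance uses the arithmetic mean over all
  distance-assigned metacells as baseline (geometric-mean option), since
  the fold-enrichment denominator is not defined upstream.
* Pseudobulk DE: cells under a 500-UMI floor are dropped, the rest are
  downsampled without replacement to the common minimum per-cell total
  (both choices configurable; the published downsampling target is
  unstated). Gene filters (expressed in ≥50% of enriched-group cells,
  ≥0.1 mean UMI) are evaluated in the enriched group, defined per gene by
  the larger normalised pseudobulk value. P-values are Mann-Whitney on
  per-cell downsampled counts — the per-cell unit is an assumption,
  flagged — corrected by Benjamini-Hochberg.
* Per-cell signature scores are the fraction of a cell's UMIs in signature
  genes: a deliberately simple, documented scorer whose outputs feed the
  bimodal-threshold finder (KDE with Scott's rule; modes must reach 5%
  prominence of the density maximum; the threshold is the density minimum
  between the two largest modes).
* Entropy uses the Shannon index in bits by default (natural log by
  option); the log base is a reporting convention and is documented
  wherever values are produced.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses rely on:
clone populations drawn from 2–3 growth-rate subpopulations (defaults
μ = 5/15/40 days, weights 0.19/0.62/0.19), fates across primary and
secondary passages, spike-in ladders spanning 10–12,500 cells with tens of
replicates per level, multinomial read sampling with per-base substitution
errors and staggered flanks, doublet/multi-integration barcode patterns,
and metacells on a latent chain with a plantable
epithelial-to-mesenchymal gradient. They do not model mouse physiology,
tumour spatial structure, PCR chimeras, index hopping, GC bias, or
scRNA-seq chemistry beyond barcode and doublet logic — so passing tests
demonstrate correctness of the analysis under the stated sampling models,
not robustness to every artifact of real libraries. Phred qualities are
constant Q37 with a configurable corruption rate to Q20, since the
pipeline only thresholds at Q30.

Problem sizes in the test and acceptance suites are chosen to exercise the
stated regimes directly: the collision bound runs on the full pooled
2×10⁶-barcode library with 100 draws of 1,000; mixture recovery runs at
the full 19,303-clone scale over 50 replicates; the gamma closed form is
checked at 10⁴ clones; the DE null at 200 replicates of 200 genes; the
end-to-end smoke run uses two models × three passages at 3×10⁴ reads per
sample.

## Known limitations

* Only read 1 is parsed for barcodes; read 2 is generated as the mate's
  reverse complement and can be cross-checked but carries no extra
  information under the substitution-only error model.
* The calibration extrapolates beyond the spike-in ladder for clones
  larger than 12,500 cells; the log-log linearity assumption is untested
  outside the ladder range.
* The per-model "strong and highly variable" gene thresholds for module
  clustering default to permissive values (`min_mean=0`, `min_cv=0`) and
  should be set per dataset.
* `fit_gaussian_mixture` fits homoscedastic-free univariate components
  only; multivariate state was never needed for doubling times.
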