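# Methods

## Differential expression

Each feature is modeled as negative-binomial with log link,
`log mu = log c_s + X beta`, where `c_s` are median-of-ratios size
factors (computed over features nonzero in every sample, rescaled to
geometric mean 1; a nonzero-entry fallback handles very sparse matrices)
and `X` contains an intercept, a 0/1 status column (case = 1, so positive
log2 fold changes mean higher in cases) and the caller's covariates
(numeric covariates centered, factors dummy-coded). Fitting is iterated:
a Poisson GLM provides initial means, the dispersion `alpha` solves the
Pearson chi-square equation `sum (y - mu)^2 / (mu + alpha mu^2) = n - p`
(floored at 1e-8), and the NB GLM is refitted with one dispersion
refinement. The Wald statistic for the status coefficient is referred to
the standard normal — a large-sample choice, adequate at the cohort sizes
the calibration benchmark uses — and BH adjustment runs across tested
features only. Features that are all-zero, separated or non-convergent
are reported untested rather than raised; an optional independent filter
(base-mean quantile, default off so the BH denominator is reproducible)
can remove weakly expressed features from testing.

Deliberate departures from the DESeq2 lineage: no Cox-Reid/MAP dispersion
shrinkage (an optional trend-shrinkage toward an `a0 + a1/mean` fit is
available but off by default), no fold-change shrinkage (raw MLE LFCs),
no outlier replacement. An independent cross-check against pydeseq2 on a
small simulated cohort (test suite) shows near-identical fold changes
(r > 0.98). The "rlog-like" transform used for correlations, PCA and
signature scoring is `log2(count / size_factor + 1)` — a monotone
pseudo-log, not the shrinkage-based regularized log; the name flags the
difference.

Type-I calibration is measured, not assumed: under a simulated NB null
(2000 features, 50 + 50 samples, dispersion 0.1) the fraction of Wald
p < 0.05 must land in [0.03, 0.07].

## Network construction

Candidate pairs are database entries whose miRNA and gene are both
significant at FDR < 0.05, deduplicated across source databases with the
source union kept; a pair counts as experimentally validated if any
contributing source is a validated-class database. Edges require Pearson
r < -0.7 and p < 0.05 over the intersection of samples assayed on both
layers. Numerical conventions, all deliberate:

* both admission inequalities are strict (a pair at exactly the
  threshold is rejected);
* statuses are pooled for the correlation — pooling is what makes
  DE-driven anticorrelation detectable at a ~11-sample intersection; an
  option restricts to one status;
* the correlation p-value is two-sided (direction is already enforced by
  the r threshold);
* pairs with a constant expression vector are skipped with a logged
  reason rather than treated as zero correlation.

For the degree comparison, each transcript's edges are aggregated by the
arithmetic mean of edge r values (a pooled per-edge variant is provided;
the aggregation is genuinely underdetermined in this kind of reporting),
split into degree > 1 versus degree = 1 and compared with a two-sided
Mann–Whitney U — exact enumeration when both classes have ≤ 8 values and
the values are tie-free in practice, tie-corrected normal approximation
otherwise. Prioritization is two-tiered: targets of ≥ 2 miRNAs, and
within those the targets with ≥ 1 validated edge.

## Over-representation analysis

Upper-tail hypergeometric mass `P(X >= k)` for `k` annotated genes in a
query of `n` drawn from a background of `N` with `K` annotated, with the
background fixed to the genes expressed in the mRNA dataset (standard ORA
practice; a genome-wide background would overstate enrichment for
biopsy-expressed sets). Sets are intersected with the background before
testing; BH runs within each query's result list, matching per-figure
FDR reporting. Both gene-ratio conventions (`k/n` and `k/K`) are emitted
because dot-plot captions in this literature use them interchangeably.
The optional redundancy collapse is a greedy Jaccard filter
(threshold 0.5, best-p kept) — a deliberately simple stand-in for
semantic-similarity reduction, labeled as such.

## Cell-type scoring and composition correction

Signatures are the top-10 atlas-enriched miRNAs per cell type (ties at
the cutoff broken lexicographically, logged). The per-sample score is an
ssGSEA-style running sum: features ranked by expression (average ranks
for ties), in-set features advance a weighted CDF with weight
`rank^tau`, out-of-set features a uniform CDF, and the score is the
signed maximum deviation between the two. `tau = 0.25` by default;
`tau = 0` gives the unweighted, hand-checkable form. The score depends on
ranks only (invariant to monotone per-sample transforms) and is reported
unscaled across samples. This is a self-contained running-sum statistic,
fully specified here, chosen over kernel-density variants because the
workflow needs only a monotone per-sample summary of signature rank
concentration.

Composition correction appends the signature scores as continuous
covariates to the NB GLM and reports which previously significant
features (FDR < 0.1) survive. Constant or collinear score columns raise
with their names — silently dropping them would hide a broken signature.

## Synthetic cohorts

The generator's defaults are the emulated study design: 10 controls and
33 cases with miRNA counts on every sample and mRNA counts on a 5 + 6
subset; two cell types (epithelial, T cell) with Dirichlet composition
(8, 2) in controls and (5, 5) in cases — epithelial loss with T-cell
influx; 100 planted repressions with slope 1.5; NB dispersion 0.05;
library-size log-sd 0.15; age ~ Uniform(2, 17) years and sex ~
Bernoulli(1/2) for a pediatric cohort. Each feature's latent log2
abundance is the composition-weighted mixture of cell-type baselines
(Uniform(4, 10) log2, i.e. ~16–1024 expected counts, the band where
features are reliably quantified) plus an optional direct status effect
(magnitude Uniform(1, 2), random sign, 20% of miRNAs, 15% of genes,
assigned to non-marker features so direct and composition-driven effects
stay separable); 10% of features per cell type are markers, gaining the
marker effect (3 log2 units) in their own type and losing it elsewhere —
strongly cell-type-exclusive miRNAs are a minority of the miRNome.
Planted repressions subtract `slope * (x_m - mean(x_m))` from the target
gene's latent mean, where `x_m` includes a per-sample latent noise term
(sd 0.3 log2); without that term planted pairs would have no within-group
latent variance and anticorrelation would be a pure two-cluster artifact.
Regulating miRNAs are drawn from the direct-effect set (the workflow only
pairs differentially expressed features) and ~20% of target genes carry
two regulators so the degree comparison has both classes. Counts are
gamma-Poisson draws around `libsize * 2^latent`.

The target database lists each true pair in each prediction source with
probability 0.9 and each validated source with probability 0.4, and adds
`decoy_rate x n_true_pairs` unique random non-true pairs (default 4:1)
under one prediction source each. The gene-set collection contains a
module of repression targets and a module of case-upregulated genes among
random sets; the atlas gives every miRNA one home cell type on a strictly
higher value support than its away values (markers on top), which makes
per-cell-type top-k signatures disjoint by construction; the prioritized
gene list mixes case-upregulated genes, repression targets and unaffected
genes.

What the generator does *not* emulate: count-level library composition
artifacts, miRNA families and shared seed sequences, isomiRs,
UTR-sequence-dependent targeting strength, batch effects, or any
correlation between age/sex and expression. Passing tests therefore show
that the statistics are calibrated and that the workflow recovers planted
structure under realistic noise — not that the pipeline is robust to
every artifact of real sequencing data.

## Benchmark scenarios and their sizes

Problem sizes are chosen to keep the full benchmark suite around two
minutes on one CPU: 2000 feature fits for type-I calibration, 1000 random
queries for ORA uniformity, 200 features at 60 + 60 samples for
fold-change recovery (planted effects balanced ±1 so normalization cannot
absorb them; estimates sign-aligned before averaging), 10 seeds of the
24-sample recovery scenario, 50 seeds of the 20 + 20 correction scenario
(100 miRNAs so each cell type has exactly 10 markers, matching the
signature size).

## Known limitations

* Pair-level recovery precision under the default confounded conditions
  sits near 0.78: decoy database pairs between markers of different cell
  types, and between features whose differential expression is
  composition-driven or co-regulated, are *genuinely* anticorrelated, and
  no anticorrelation filter can separate them from planted repressions.
  This is the method's honest behavior in mixed tissue, and the reason
  the composition-corrected retest exists downstream.
* The Wald test's normal reference is anticonservative for very small
  groups (< ~8 per arm); the calibration benchmark covers 50 + 50.
* The Pearson p-value's t reference agrees with the exact permutation
  distribution to ~0.01 in the tails at n = 7–8 but can drift mid-range
  for samples with influential points.
* Gene identifiers are opaque strings; harmonizing miRNA accessions and
  gene symbols across count matrices, databases and atlas is the
  caller's responsibility.
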