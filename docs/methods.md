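# Methods

This note documents the models, numerical choices and limitations of the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mixture model and factorization

Bulk expression is modelled as a non-negative mixture
`X = W H + ε`, with k = 3 factors read as immune, activated-stroma and
tumour compartments. The factorization minimises the generalised
Kullback–Leibler divergence by the classical multiplicative updates; this
variant was chosen (over a Frobenius objective) to match the consensus-NMF
tradition this style of tumour subtyping descends from. Implementation
details that matter for reproducibility:

- denominators in the updates are guarded by ε = 1e-12;
- the objective is evaluated every iteration and must be non-increasing
  (a property test checks this numerically);
- convergence is declared when the relative per-iteration decrease falls
  below `tol` (default 1e-6 in the library call, 1e-5 in the pipeline);
  non-convergence flags the model but still returns it;
- the best of `n_restarts` (default 5) seeded random restarts is kept, and
  the restart seeds and final divergences are recorded in the model;
- `W` columns are rescaled to unit L1 norm with compensating scaling of
  `H`, so basis weights are comparable across genes.

Before factorization the matrix is restricted to the top-N genes by median
absolute deviation (default 1500, exposed in config); MAD was preferred to
variance for robustness, with the caveat noted under Limitations that MAD
down-weights markers of minority classes. Rank diagnostics (cophenetic
correlation of run-consensus matrices, reconstruction error per k) support
the fixed choice k = 3 rather than replace it.

## Single-sample enrichment scores

The ssGSEA statistic is the running-sum integral form: for a sample, genes
are ranked by decreasing expression and
`ES = Σᵢ (P_in(i) − P_out(i))` where `P_in` accumulates in-set rank weights
`r^α` (top gene has r = N) normalized by their total, and `P_out`
accumulates `1/(N−|S|)`. α defaults to 0.25 and is configurable; α = 0
gives the unweighted statistic with the exact antisymmetry
`ES(S) = −ES(S̄)` on tie-free data, which the tests exploit as an oracle.
Ties in expression are broken by gene-identifier lexicographic order so
scores are bit-reproducible. Normalization modes: none (default),
global-range (divide by the score range of the whole matrix), z-by-set.
Sets with empty intersection with the gene universe, or covering it
entirely, produce per-set error records rather than failing the call.

## Class discovery, subtype split, projection

Discovery clusters samples on the exemplar genes of the immune factor by
consensus hierarchical clustering: `n_resamples` (default 100) subsamples
of `sample_fraction` (default 0.8) of the samples, average linkage on
1 − Pearson distance, co-assignment frequencies among co-sampled pairs,
final partition by cutting the tree of 1 − consensus at two clusters. The
cluster with the higher mean immune score is the immune class.

The active/exhausted split is an exact 1-D two-means of the
activated-stroma score within the immune class (all split points on the
sorted values are scanned, so the optimum is deterministic; ties break to
the lower split index). The higher-stroma cluster is exhausted.

Projection of an external cohort rank-normalizes each sample over the
shared exemplar genes (average ranks on ties, scaled to [0, 1]) and assigns
the nearest class centroid by Pearson correlation, requiring ≥ 50% exemplar
overlap; an alternative mode projects samples onto the reference basis by
NNLS and assigns the immune class when the immune factor contributes the
largest share of predicted expression on the shared genes (shares, not raw
coefficients, are compared because basis columns are differently scaled on
a gene subset). Which projection mode was used is recorded in the outputs.
Projected immune samples are re-split on the projected cohort's own stroma
scores, because enrichment-score scales are not comparable across cohorts.

## Differential analysis and GSEA

Differential expression uses a vectorized Welch t-test (or Wilcoxon
rank-sum) on log-scale input with the package's own Benjamini–Hochberg
step-up (`adjᵢ = min_{j≥i} m·p⁽ʲ⁾/j`, capped at 1; statsmodels is used as an
independent cross-check in the tests, never as the implementation). A
feature passes at adjusted p < 0.05 and |log₂FC| > 1 (both strict); the
fold-change threshold is read as two-sided since both up- and
down-regulated lists are of interest. No empirical-Bayes variance
moderation is applied — the tests are exactly what they claim to be — and
this is a deliberate non-goal. Zero-variance features get a guarded p
(1 when means agree, 0 otherwise) and a flag.

Preranked GSEA uses the weighted-KS maximum-deviation statistic with
gene-label permutation (not phenotype permutation, whose small subgroup
sizes would make it unstable), sign-stratified NES and FDR as in the
standard procedure. A known artefact of sign stratification is a coarse
nominal p for sets whose observed ES sign is rare among permutations (the
p floor is 1/(1 + strata size)); the FDR column is the quantity to filter
on. Permutation counts below 10 are rejected.

## Genomic scores

Copy-number inputs are SEG-style segments in log₂ relative copy-number
space. Burden is the length-weighted fraction of covered bases with
|seg_mean| > 0.1 (strict); gene-level calls use the length-weighted mean
over overlapping segments against ±0.3 (strict, so exactly 0.3 is
neutral); the aneuploidy score counts arms whose length-weighted mean
exceeds ±0.1, over an embedded approximate-hg38 table of the 39
non-acrocentric autosomal arms. Using a thresholded weighted mean is an
approximation to methods that work from discrete absolute-copy-number
calls, which need allelic data this pipeline does not consume. Mutation
frequency filtering keeps genes non-silently mutated in strictly more than
5% of samples, counting each sample once.

Mutational signatures are extracted from 96-trinucleotide-context count
matrices by the same KL-NMF core; signature profiles are column-stochastic
and exposures are rescaled so `signatures @ exposures` reconstructs
expected counts. Extractions are reported with a cosine-similarity match
against the packaged reference table. That reference is **synthetic**: five
parametric caricatures (two APOBEC-like TCW profiles, a CpG clock-like
profile, a broad C>A profile, a flat background) built in code — adequate
for validating extraction, not for annotating real tumours against curated
catalogues.

## Cohort statistics

Pearson chi-square without continuity correction (matching how the
published clinical tables were evidently computed), Fisher's exact test for
2×2 tables, one-way ANOVA with Fisher's LSD pairwise comparisons on the
pooled within-group mean square (unadjusted, as the procedure is defined),
and the rank-sum test (exact enumeration when n ≤ 12 and tie-free,
otherwise the normal approximation with tie and continuity corrections).
Clinical covariates keep "Unknown" as a genuine level by default because
the published degrees of freedom are only reproducible that way; a
drop-unknown option exists. Survival uses lifelines' product-limit
estimator (with Greenwood variance computed alongside) and the multivariate
log-rank test. Propensity matching fits a plain logistic model by IRLS
(quasi-Newton fallback for near-collinear dummies), then greedily matches
treated to control units 1:1 without replacement within a caliper of
0.2 × sd(logit PS), visiting treated units in seeded random order;
standardized mean differences before/after are reported. Genuine
separation (all fitted probabilities degenerate) is an error naming the
worst covariate. Which risk factors enter the matching is a configuration
choice; the pipeline default is age, HPV status, stage and histology.

For between-group alteration tests, Fisher's exact fallback applies only to
2×2 tables; 2×g tables with low expected counts keep the chi-square and are
flagged, since no exact r×c test is available in the dependency set.

## Synthetic cohort: what it emulates and what it does not

Defaults emulate the training conditions: 293 samples with class
proportions (0.52, 0.26, 0.22) for active-immune / exhausted / non-immune,
2000 genes, noise sd 0.25 on a loading scale of 3, exponential survival
with hazards (0.010, 0.025, 0.016) per month and uniform censoring on
[0, 120] months, per-class copy-number profiles in which the exhausted
class has the largest altered fraction and the non-immune class the most
segments, and per-class mutational-signature mixtures over the synthetic
reference.

Design points that shape what the tests can show:

- **Gene biology is fixed across cohorts.** `W_true` is drawn from a
  dedicated `biology_seed` (default 1618) independent of the cohort seed,
  because a gene's compartment loading is a property of the gene, not of
  one cohort; this is what makes a reference learned on one cohort
  transfer to an independently generated one.
- **Identifiability is anchored.** Half of each immune/stroma block are
  pure markers (bright, expressed in no other compartment); the other half
  carry a low-level tumour-compartment expression, as most genes do in real
  bulk data. Without pure markers the factor cone edges are not unique and
  no NMF (ours or any other) recovers the planted loadings exactly; without
  the leaky half, samples lacking a compartment would have no correlated
  structure on the exemplar genes and consensus clustering could not
  separate them. Housekeeping genes put near-equal shares on every factor.
- **Every tumour has stroma.** The stroma coefficient has a nonzero
  baseline in all classes (0.30 / 1.20 / 0.35), with the exhausted class's
  activated response on top — this keeps stroma genes variable enough to
  survive the MAD filter and the stroma factor well-conditioned.
- Noise is Gaussian truncated at zero, preserving the non-negativity the
  factorization requires. Clinical "Unknown" is generated as a real third
  level with class-dependent probability. The leukocyte fraction is
  anti-correlated with the per-sample segment count within each class
  (coefficient sized for a rank correlation near −0.35).

What it does **not** emulate: batch effects, library-size or array
normalization artefacts, HPV integration biology, gene–gene co-expression
beyond the factor model, read-level noise, or realistic mutation positions
(coordinates are uniform placeholders). Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to everything real data does.

## Problem sizes

The default test and acceptance runs use the full 293-sample, 2000-gene
cohort for discovery and projection, 60 catalogues × 400 mutations for
signature recovery, and 1000 null features for error-control checks; unit
tests use a 120-sample, 800-gene cohort processed once per session. These
sizes were chosen so the complete suite exercises the full pipeline in
about half a minute on a single CPU.

## Known limitations

- KL-NMF recovery of the stroma factor is the weakest of the three (its
  signal lives in a minority of samples atop a shared baseline); matched
  cosines sit around 0.95–0.98 rather than 0.99+.
- The MAD pre-filter can drop minority-class markers whose median
  deviation is small; the generator compensates by making canonical
  markers bright, real analyses may need a different filter.
- Sign-stratified GSEA p-values are coarse when one sign dominates the
  permutation null.
- The greedy caliper matching is order-dependent by construction; the
  order is seeded and recorded.
- Arm-level aneuploidy from thresholded weighted means differs from
  ABSOLUTE-style discrete calls on real data.
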