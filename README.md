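# immunodissect

Immune classification of bulk tumour expression by NMF virtual
microdissection, with the genomic scores, multiomics integration rules and
cohort statistics that characterize the resulting classes. The package is
aimed at computational oncologists who want a transparent, fully testable
implementation of this style of analysis: bulk tumours are mixtures of
malignant, stromal and immune cells, and the composition of that mixture —
not any single marker — is what separates tumours likely to respond to
immune-checkpoint blockade from those that will not.

## The method

Given a non-negative gene × sample expression matrix `X`, the pipeline:

1. **Virtual microdissection.** Factorize `X ≈ W H` (`W ≥ 0` gene × k basis,
   `H ≥ 0` k × sample coefficients, k = 3) by multiplicative updates under
   the generalised Kullback–Leibler divergence
   `D(X‖WH) = Σᵢⱼ [Xᵢⱼ log(Xᵢⱼ/(WH)ᵢⱼ) − Xᵢⱼ + (WH)ᵢⱼ]`,
   best of several random restarts. The three factors are interpretable as
   tumour, stroma and immune compartments.
2. **Immune factor and exemplar genes.** Score every sample with
   single-sample GSEA (rank-weighted running-sum statistic,
   `ES = Σᵢ (P_in(i) − P_out(i))` with weights `r^α`, α = 0.25) on an
   immune gene panel; the factor whose `H` row correlates best with this
   score is the immune factor, and its most specifically weighted genes
   (basis weight ratio ≥ 2 over any other factor) are the exemplar genes.
3. **Immune class and subtypes.** Consensus-cluster samples on the exemplar
   genes (resampled average-linkage clustering under 1 − Pearson distance);
   the cluster with the higher immune score is the *immune class*. Within
   it, a 1-D two-means split of the activated-stroma score separates the
   *exhausted* subtype (stroma-high) from the *active immune* subtype.
4. **Projection.** External cohorts are assigned by rank-normalized
   nearest-centroid correlation on the shared exemplar genes (or
   non-negative projection onto `W`), then re-split on their stroma scores.
5. **Characterization.** Differential expression (Welch t, BH FDR < 0.05,
   |log₂FC| > 1) with preranked GSEA; copy-number burden (fraction of bases
   with |log₂ CN| > 0.1), gene gain/loss calls (±0.3, strict), arm-level
   aneuploidy scores; 96-context mutational-signature extraction by the
   same KL-NMF; miRNA/lncRNA network joins and ≥ 2-of-N multiomics gene
   integration; chi-square/Fisher clinical tests (with "Unknown" as a
   genuine level), ANOVA + LSD, Kaplan–Meier/log-rank survival and
   propensity-score-matched comparisons.

Because the real cohorts behind this kind of study are not redistributable,
the package ships a first-class synthetic-cohort generator
(`immunodissect.synthetic`) that plants the exact structure the analysis
assumes — three expression factors, class-linked clinical covariates and
hazards, per-class copy-number profiles, signature-mixture mutation
catalogues — with the ground truth recorded, so every stage is validated by
parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort (293 samples, 2000 genes):

```bash
python analysis/01_simulate_cohort.py      --seed 0
python analysis/02_discover_immune_class.py --seed 0
```

prints

```
discovered class proportions:
               count  percent
class
active_immune    132    45.05
non_immune        84    28.67
exhausted         77    26.28
```

i.e. the clustering finds an immune class of 209/293 samples (71%), split
into active-immune and exhausted subtypes; comparing
`results/analysis/class_labels.tsv` with the generator's `truth.json` shows
the three-class assignment recovers the planted labels with ≥ 0.9 accuracy.
`03_validate_projection.py` projects an independently generated cohort onto
the learned reference, and `04`–`06` produce the differential, genomic,
network and survival tables (for example, at seed 0 the exhausted class has
the largest mean fraction of genome altered, the leukocyte fraction
correlates negatively with segment counts within each class, and the
three-class log-rank test on the planted hazards gives p ≈ 1e-05).

The same workflow is available as a CLI (`immunodissect run-all --seed 0`)
or programmatically via `immunodissect.pipeline.run_pipeline`.

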