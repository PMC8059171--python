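# paraspec

Region-specific expression of duplicated genes across the territories of
the human central nervous system.

Gene duplication — whole-genome duplication (WGD) in the early vertebrate
lineage and small-scale duplications (SSD) throughout evolution — is a
major source of expression diversity between tissues. Within a single
organ, the question becomes sharper: are paralogs, and which classes of
paralogs, preferentially expressed in particular anatomical regions?
`paraspec` implements the full analysis chain to answer this for bulk
RNA-seq of CNS regions: expression preprocessing, a permutation-calibrated
region-specificity index, duplication-category enrichment statistics,
co-expression-based classification of gene families, and paralog-pair
genomic-distance analyses — together with a synthetic-data generator that
plants known signals so every classifier in the chain can be scored
against ground truth.

It is aimed at computational biologists studying paralog evolution and
regional transcriptomes, and at methodologists who need a specificity
pipeline whose operating characteristics (false-positive rate,
sensitivity, assignment accuracy) are measurable by construction.

## The specificity index

For a gene with mean expression x_i in each of n = 7 merged CNS regions
(on the log2(RPKM + 1) scale, covariate-adjusted, negatives clipped at 0):

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

tau is 0 for uniform expression and 1 for expression confined to one
region. Because a single-organ analysis has no natural tau cutoff, the
threshold is calibrated empirically: region labels are permuted across
samples, tau is recomputed for every gene and permutation, and all
permuted scores are pooled into one null distribution. Each gene's
p-value is the proportion of pooled null scores above its observed tau;
Benjamini–Hochberg correction across genes declares region-specific genes
at q < 0.01, and the smallest tau among declared genes is the induced
threshold. A specific gene is assigned to the region with its highest
mean expression.

Downstream, 2x2 contingency tests (chi-squared, or Fisher's exact when an
expected count drops below 5) quantify enrichment of specificity across
duplication categories (WGD / SSD / ySSD / wSSD / oSSD); a topological-
overlap co-expression network clusters paralogs into modules; a family is
*homogeneous* when strictly more than 60% of its total membership falls
into one module, and *region-specific* when a strict majority of its
expressed members is specific to the same region; duplicate pairs are
classified as tandem (< 1 Mb apart), intra- or inter-chromosomal.

## Worked example

The numbered scripts under `analysis/` run the chain end-to-end on a
simulated dataset (600 genes over seven duplication classes, 13 regions x
10 samples, planted region-specific genes and homogeneous families):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_specificity.py
python analysis/04_coexpression.py
python analysis/05_families_pairs.py
python analysis/06_reconstruct_enrichments.py
```

Step 03 prints

```
164/600 genes region-specific at FDR < 0.01 (tau threshold 0.302); sensitivity vs planted truth 0.80
```

i.e. the permutation-calibrated procedure induces a tau threshold of
0.302 on this dataset and recovers 80% of the planted specific genes.
Step 04 prints

```
27 modules over 440 paralogs (256 unassigned); 40 homogeneous families (empirical p = 0.000999, null max 7); recovery vs planted truth: sensitivity 0.81, precision 0.97; ...
```

the observed homogeneous-family count (40) exceeds every one of 1000
label permutations (null maximum 7), giving the smallest reportable
empirical p-value, 1/1001. Step 06 reconstructs the study-scale
enrichment odds ratios from the published group sizes of the 16,427-gene
universe — e.g. paralogs vs. singletons OR 1.47, young SSDs within SSDs
OR 1.62 — and the Bonferroni cutoffs (0.05/78 = 6.41e-4 for region-pair
tests, 0.05/7 = 7.14e-3, 0.05/3 = 1.67e-2).

The same pipeline is available as a CLI (`paraspec simulate | preprocess |
tau | enrich | modules | families | pairs | run-all`) and as a library
(`paraspec.pipeline.run_pipeline`).

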