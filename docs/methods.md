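# Methods

## Scope and data model

`paraspec` analyses a genes x samples abundance matrix (RPKM-like,
non-negative), a sample table mapping each sample to one of 13 CNS
territories and carrying covariates (sequencing platform, age, sex, three
genotype principal components), and a gene annotation table (paralog /
singleton status, duplication category WGD / SSD / WGD-SSD / unannotated,
SSD age class ySSD / wSSD / oSSD, family id and total family size,
phyletic age, chromosome and start coordinate). The 13 territories merge
onto 7 regions by a fixed anatomical map (cerebellar, cortical and
basal-ganglia samplings pooled; amygdala with hippocampus; hypothalamus,
spinal cord and substantia nigra kept separate); all specificity scoring
happens at the 7-region level so a gene shared among close sub-regions is
not spuriously scored as broadly expressed.

## Preprocessing

1. **Filtering.** A gene is kept iff its variance across all samples is
   positive and its mean RPKM reaches 0.1 in at least one of the 13
   territories (`low_expr_rpkm`, default 0.1 RPKM). The variance filter
   runs first; the order is observationally irrelevant but fixed for
   reproducible logs.
2. **Transform.** v -> log2(v + 1).
3. **Covariate adjustment.** Per gene, ordinary least squares of the log
   values on an intercept, treatment-coded platform and sex (most
   frequent level as reference), age and the three genotype PCs. The
   output is residuals **plus the fitted intercept**, so between-gene
   mean structure survives while covariate-attributable variance is
   removed. Constant covariate columns are dropped from the design (they
   carry nothing to adjust for); a rank-deficient design is an error
   naming the collinear columns. Adjusted values may be negative and are
   passed through unchanged — clipping is the specificity stage's
   responsibility.
4. **Region means.** 13-region means are per-territory sample means;
   7-region means are *unweighted averages of the constituent 13-region
   means*, not pooled sample means, so unequal territory sample sizes do
   not skew a merged region's profile.

## Specificity

tau = sum_i (1 - x_i/max_j x_j) / (n - 1) over the n = 7 region means,
clipped at 0 before scoring. Clipping preserves the [0, 1] range and the
max-normalisation semantics in the presence of adjustment-induced
negative means; a gene whose clipped means are all zero has no defined
tau and is excluded from calls.

**Null and threshold.** Sample-to-territory labels are permuted uniformly
(at the 13-territory level, then merged, so the null respects the unequal
territory sizes feeding each merged mean); tau is recomputed for every
gene and permutation (`n_permutations`, default 1000) and all scores are
pooled into a single null of size n_permutations x n_genes. The pooled
null gives p-value resolution far finer than 1/n_permutations; a per-gene
null is available behind a flag. The empirical p-value uses the
(c + 1)/(N + 1) estimator with a strictly-greater count (ties count as
not-higher), so no p-value is exactly zero; the plain proportion is
available behind a flag and differs negligibly at pooled-null sizes.
Benjamini–Hochberg across genes declares specificity at q < `fdr_alpha`
(default 0.01). Because the null is shared, p is monotone in tau and the
called set is exactly {tau >= threshold}; the reported threshold is the
smallest tau among called genes (+inf, with a warning, when nothing is
called). Each called gene is assigned the region with its largest mean;
exact ties go to the lexicographically first region name with a logged
warning.

**Summaries.** Expression bins are 1-unit intervals of log2(RPKM + 1) of
each gene's maximal region mean, with an open top bin at log2(128) = 7
(>= 127 RPKM); per bin and duplication class the count and percent
specific are reported. Phyletic-age summaries report per distinct age the
count and tau quartiles.

## Enrichment statistics

2x2 tables (tested group vs rest-of-universe x property yes/no) are
tested by chi-squared without continuity correction — at the group sizes
involved the correction is immaterial — falling back to two-sided
Fisher's exact when any expected cell count is below 5. The odds ratio is
the unconditional cross-product ratio ad/bc (infinite, flagged, when
bc = 0). Bonferroni thresholds are alpha/n_tests for the declared test
family. Tests touching homogeneous-family membership accept an explicit
exclusion set (the members of homogeneous families outside their family's
main module) rather than hard-coding that rule. Rank comparisons of tau
between groups use the two-sided Mann–Whitney U with normal
approximation and tie correction. The tau linear models are OLS of tau on
maximal expression plus class indicators (paralog status over all genes;
duplication type within paralogs; age class within SSDs), erroring on
collinear designs.

## Co-expression modules and family homogeneity

Restricted to paralogs: Pearson correlation across all samples ->
unsigned soft-thresholded adjacency a_ij = |cor|^beta (signed variant
available; beta is the smallest value in 1..20 whose network reaches a
scale-free fit R^2 of 0.8, falling back to 6) -> topological overlap
t_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 - a_ij) ->
average-linkage hierarchical clustering of 1 - t.

The tree is cut top-down deterministically: a subtree is always split
while its top merge height exceeds a tightness height
(cut_height − 0.0125·(1 + deep_split)); below that, it is split only
when its top merge is separated from both children by a minimum gap
(0.25·(1 − deep_split/5)) — a deep valley in the dendrogram — and never
when a resulting child would fall below `min_module_size`. Accepted
subtrees become modules; fragments below `min_module_size` get label 0
(unassigned). Defaults cut_height = 0.99, deep_split = 4,
min_module_size = 2 are chosen for many small, tightly co-expressed
modules, since roughly half of annotated families have only two members.
Labels are canonicalised by descending module size, making the partition
invariant to gene input order. Module inference runs on the adjusted
matrix by default (a flag selects raw log2 values).

A family is **homogeneous** when strictly more than `homogeneity_fraction`
(default 0.60) of its *total* membership — counting members absent from
the expression matrix — shares one non-zero module; the modal module with
ties broken conservatively (a tie means heterogeneous). Members of
homogeneous families outside the main module form the exclusion set for
downstream tests. Significance of the homogeneous-family count is
assessed by permuting module labels across paralogs (preserving the label
multiset) and reclassifying; empirical p = (#{null >= observed} + 1) /
(n_permutations + 1), so the strongest reportable value at 1000
permutations is 1/1001.

## Families and pairs

A family is **region-specific** when strictly more than half
(`family_specific_fraction`, configurable) of its *expressed* members are
declared specific to the same region (modal region among its specific
members; a modal tie disqualifies). The expressed-member denominator
parallels the treatment of expressed paralogs elsewhere; total-size
denominators are a config change away.

Duplicate pairs are kept only when listed in both orientations with the
same duplication category (conflicts dropped and logged), deduplicated to
the lexicographic orientation. Distance classes use start coordinates —
deterministic and strand-free; the anchor is a config option: different
chromosomes -> inter-chromosomal; |delta start| < `tandem_bp` (default
1 Mb) -> tandem; otherwise intra-chromosomal. Per duplication category,
among pairs with both members specific, the fraction assigned to the same
region is reported with its (often small) denominator.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with ground truth for every downstream classifier. Log2 RPKM for gene g,
sample s in merged region r:

    x_gs = baseline_g + regioneffect_g(r) + covariates_gs + noise_gs

* **Baseline**: Normal(`baseline_mean_log2` = 3, `dispersion` = 1.5) plus
  a class shift (ySSDs 1 log2 unit weaker, reflecting the weak expression
  of young duplicates). RPKM = 2^x; noise (sd 0.5) is therefore
  multiplicative on the RPKM scale, so the log2(RPKM + 1) analysis
  transform compresses weak-gene variability as it does for real
  abundance data.
* **Planted specificity**: with class-specific probability (defaults
  mirror the observed per-class rates, 13.9%–28.6%), a gene's target
  region — drawn at the 7-region level, so merging never splits a planted
  signal — is elevated by log2(`specificity_effect`), i.e. a
  multiplicative fold change (default 4) of the region mean.
* **Families**: paralogs are grouped within class; sizes are 2 with
  probability 0.47 and 3 + Geometric(0.55) − 1 otherwise (mean ≈ 3,
  matching families-per-paralog bookkeeping); a family may count one
  unexpressed member (probability 0.2) in its total size. A fraction of
  families (`frac_homogeneous_families`, default 0.03) is homogeneous:
  members share one latent region profile (sd 1.0) plus small
  member-specific deviations, and share one specificity status (with
  probability 0.23 the family is planted region-specific to a common
  target). Heterogeneous families' members are planted independently,
  except that specific members share the family target with a
  class-dependent probability (0.59 for ySSD down to 0.31 for WGD),
  emulating the shared specificity of young duplicate pairs.
* **Covariates**: platform, sex, age, three genotype PCs with per-gene
  coefficients (scales 0.3 / 0.1 / 0.005 per year / 0.1), removable by
  the adjustment stage.
* **Coordinates**: uniform over 22 autosomes; size-2 families are placed
  in tandem (< 1 Mb) with class-dependent probability (0.5 for ySSD down
  to 0.05 for WGD).

Default class counts are the annotated 16,427-gene universe (6092
singletons, 5114 WGD, 1192/1260/1267 y/w/oSSD, 966 WGD-SSD, 536
unannotated); tests and the acceptance script scale the gene count down
(600–2000 genes) and use 10–30 samples per region to keep runtimes in
seconds while preserving class proportions. The generator does **not**
emulate read-level noise, mappability artifacts of segmental
duplications (which bias quantification of very young duplicates in real
short-read data), RNA-integrity effects, or correlated covariates; a pass
on synthetic data therefore demonstrates the pipeline's statistical
behaviour under its model assumptions, not robustness to those real-data
pathologies.

## Calibration and recovery measurements

Two standard Monte-Carlo measurements accompany the pipeline (in the
acceptance script and test suite):

* **Null calibration** uses a generator configuration with nothing
  planted — per-class specificity fractions 0 *and* no homogeneous
  families, since a shared family region profile is genuine region
  structure and would make the labels non-exchangeable. On such data the
  specific-call rate at q < 0.01 is essentially zero (the pooled-null BH
  procedure controls the family-wise error under a global null).
* **Planted recovery** uses 4-fold elevations, 30 samples per region and
  2000 genes, again without homogeneous families: the family profile is
  real (untracked) region structure, and with it enabled every apparent
  false positive is in fact a homogeneous-family member with a genuinely
  region-skewed profile. Under the clean configuration the procedure
  reaches sensitivity ~1.0 at realised FDR well under 0.05 with
  region-assignment accuracy ~1.0.

## Numerical conventions

Result tables are TSV with a provenance header (version, seed, config
hash) and floats at 6 significant digits; reruns under one seed are
byte-identical. All randomness flows through `numpy.random.default_rng`
seeded from the run configuration. GCT input is fixed to version 1.2;
genes present in expression but absent from the annotation are dropped
with a logged count (the analysis is defined on the annotated universe).

## Known limitations

* The tree-cut heuristic is a deterministic simplification of dynamic
  tree cutting; its two knobs are mapped from `deep_split` and it does
  not reassign stray leaves to nearby clusters.
* The pooled null assumes genes are exchangeable under label permutation;
  genes with extreme mean-variance behaviour contribute asymmetrically to
  the null tail.
* Family homogeneity with the total-size denominator cannot reach the
  strict 60% bar for families whose unexpressed members alone exceed 40%.
* Differential expression between region pairs is out of scope (an
  external tool's job); only the downstream enrichment machinery is
  provided.
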