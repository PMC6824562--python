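# Methods

`phosphodiff` reimplements, as a tested library, the downstream analysis of a
spike-in (super-SILAC) quantitative proteomics and phosphoproteomics study of
cultured cell lines: four prostate lines — one benign immortalized reference,
one castration-sensitive (CS) line and two castration-resistant (CR) lines —
each measured in three replicates against one common heavy-labeled reference
proteome. Every sample's quantification is therefore a linear H/L-style ratio
to the same denominator, which makes ratios comparable across samples without
further between-sample calibration.

## Ingest and filtering

MaxQuant-style tables are read with configurable column-name templates
(`Ratio H/L normalized {sample}`, `iBAQ {sample}`, …) because column dialects
drift across search-engine versions. Zeros in ratio and intensity columns are
decoded as missing — the "not quantified" convention — so a "valid value"
means a nonzero ratio. Rows flagged `+` as potential contaminant, reverse
(decoy) hit, or "only identified by site" are discarded before any analysis.
Phosphosite rows are keyed `ACCESSION_<residue><position>` (residue ∈ S/T/Y,
1-based position); when ratios are split by phosphorylation multiplicity
(`___1/___2/___3`), the multiplicity with the fewest missing values wins, row
by row, because downstream stages need one value per site per sample. No
localization-probability filter is applied; the probability is carried
through for user-side filtering.

The quantification ("valid value") filter keeps a feature only if it has at
least `min_valid` (default 2) valid values out of the replicates of **every**
cell line. This is deliberately conservative: it guarantees every test below
has at least two observations per group, and it removes any need for
missing-value imputation, which the pipeline never performs. The rejected
features are not thrown away — they feed the presence/absence rescue.

## Normalization and global structure

Ratios are base-2 logarithmized and z-scored. The normalization axis is a
recorded configuration value; the default is per-sample (column) z-scores,
which removes residual channel-mixing offsets between samples. Per-feature
z-scoring is available for sensitivity analysis. Zero-variance slices
normalize to zeros rather than erroring, so degenerate inputs pass through.
The operation order is fixed — artifact filter → valid-value filter → log2 →
z-score — so normalization statistics are never polluted by contaminants or
near-empty rows.

Sample clustering is average-linkage (UPGMA) on Euclidean distances. With
missing values the distance of a sample pair is computed on their shared
valid features and rescaled by `sqrt(n_total / n_shared)` so that pairs with
different coverage remain comparable; a pair sharing no features is an error.
A *replicate coherence* score — the fraction of cell lines whose replicates
form exactly one subtree — summarizes whether biological signal dominates
noise.

Proteome/phosphoproteome agreement is summarized per cell line: each
phosphosite is mapped to its parent protein group via its accession, protein
values are averaged over replicates, site values over the protein's sites and
then replicates, and a Pearson correlation is computed across the proteins
shared by both layers.

## Abundance ranking and the housekeeping proteome

iBAQ intensities proxy absolute abundance. Per cell line a protein's
abundance is the sum of its replicates' iBAQ values (missing counted as
zero); the global ranking key is the median over all samples, whose rank plot
is the familiar S-shaped curve spanning several orders of magnitude. Each
line contributes its `floor(top_fraction × N)` most abundant proteins
(default top decile; ties broken by global median, then lexicographic id),
and the intersection across all lines is reported as the highly-expressed
housekeeping proteome. The ranking runs on all identified, artifact-filtered
proteins rather than the quantification-filtered subset, since absolute
abundance does not require complete ratio coverage.

## Differential and presence/absence biomarkers

All hypothesis tests run on the normalized matrix (log2-only is selectable)
and are two-sided, with direction taken from the sign of the mean difference.
Benjamini–Hochberg adjustment is applied separately per comparison family per
layer — proteome ANOVA, phospho ANOVA, each cancer-line-vs-reference test,
each CR-vs-CS pairwise test — mirroring per-analysis significance thresholds
(ANOVA q ≤ 0.01; pairwise q ≤ 0.1, both inclusive).

* **ANOVA.** A one-way fixed-effects F-test across the four cell lines per
  feature. Features where any line has fewer than two valid values (possible
  only when the upstream filter was relaxed) are reported untested.
* **Oncogenic markers.** Each cancer line is compared to the benign reference
  with a two-sample t-test — Welch by default, Student's pooled-variance
  flavor selectable — yielding per-line up/down sets; the three-way
  intersections are the common oncogenic up/down markers.
* **Resistance markers.** Features are compared between the CS line and each
  CR line. A feature is `CR_up` only if it is significant with CR mean above
  CS mean in *both* pairwise comparisons (symmetrically `CR_down`); features
  significant in only one comparison or with mixed directions are excluded.
  The benign reference plays no role here.
* **Presence/absence rescue.** Among the features rejected by the
  quantification filter, `CR_only` features have ≥ 2 valid values across the
  CR lines' samples and strictly none in the CS line's samples; `CS_only` is
  symmetric. The benign line is ignored by the rule. (The alternative reading
  in which the benign line counts toward the "sensitive context" is available
  through the function's explicit line arguments.) By construction, a feature
  passing the quantification filter can satisfy neither rule.

The F and t statistics are computed vectorized in-house (NaN-aware group
counts, means, variances) so that calibration simulations over thousands of
features stay cheap; the test suite pins them to `scipy.stats.f_oneway` /
`ttest_ind` at 1e-10 on random samples, and the BH step-up to both an
exhaustive implementation of its definition and statsmodels.

## Kinase activity

Site scores are built from **raw** (unnormalized) linear ratios: per site,
the fold change of each CR line's replicate mean over the CS line's replicate
mean; a site enters only with at least one valid value per involved line.
Only sites deregulated consistently — fold change on the same side of 1 in
both CR lines — are retained; the mean of the fold changes is min-max
rescaled to [0, 1] for reporting. A fold change exactly equal to 1 is neither
over- nor under-expression and is excluded by the rule.

The kinase statistic for m matched substrates is
`z = (mean_substrates − mean_all) · sqrt(m) / sd_all`
with a two-sided normal-tail p-value (one-sided selectable). The statistic is
invariant to affine transformations of the score vector — asserted
numerically in the tests — so the choice of scale is presentational; the
statistic is evaluated on the log2 mean fold change, which symmetrizes up-
and down-regulation, while the [0, 1] value is carried for reporting. A
kinase is significant with at least `min_substrates` (default 3) matched
sites and p < 0.05, without multiple-testing adjustment by default (BH
selectable), matching common practice for this statistic. Sites mapping to
several kinases contribute to each.

## Module activity

For a gene set, the genes matched in the matrix with complete values (a set
needs ≥ 3) are row-centered and the first principal component of their
gene×gene covariance provides per-gene weights; the per-sample module score
is the weighted sum of expression. The weight vector is unit-norm and
oriented so that it correlates positively with the set's mean expression
profile — an arbitrary but reproducible sign convention needed for a stable
heatmap. `L1`, the fraction of the set's variance explained by PC1, measures
coordination; its significance ("overdispersion") is a permutation p-value
against `n_null` random same-size gene sets drawn without replacement from
the measured complete-value universe, `p = (1 + #{null L1 ≥ observed}) /
(n_null + 1)`, seeded and reproducible. Overdispersed modules are selected at
p ≤ 0.01. Group summaries are per-module CS and CR means of the sample
scores, divided by their max absolute value so the stronger group sits at ±1
(positive = higher activity). The permutation null replaces the analytic
machinery of the original module-activity tools; it is self-contained,
seedable and directly testable for calibration. Null comparisons use a
1e-12 tolerance so that row order cannot flip the outcome.

## Over-representation

Term enrichment of a biomarker list uses the hypergeometric upper tail on
counts restricted to an explicit background — the quantification-filtered
gene universe, not the genome — with BH across the tested terms of a
collection and significance at q ≤ 0.01. A redundancy pass walks terms in
order of significance and marks a term redundant when its
background-restricted gene set overlaps a more significant kept term at
Jaccard ≥ 0.75 (configurable); this replaces proprietary "strongest
representative per annotation group" filters with a transparent rule.

## Network integration

Protein complexes are expanded into cliques — co-membership is interaction
evidence without designating a hub — and merged across resources into one
simple undirected graph keyed by primary gene symbol (protein groups with
several symbols contribute their first listed symbol). The biomarker
subgraph is the induced subgraph on the union of the resistance and
presence/absence sets of both layers, phosphosites mapped to parent genes;
nodes get a class (`protein_up/down`, `phospho_up/down`, `CR_only`,
`CS_only`, or `mixed` with the full class list kept) and the mean normalized
CR-line expression as attributes. Biomarker genes without any edge inside the
set are excluded from the graph and listed separately, as are genes absent
from the interactome. Exports (SIF, GraphML) sort nodes and edges so that
identical inputs give byte-identical files.

## The synthetic-data generator

The generator is first-class, tested code; it produces the study conditions
every test and the acceptance script run under.

* **Design:** 4 lines (benign / CS / 2×CR) × 3 replicates.
* **Abundance:** per-protein log10-iBAQ follows a logistic quantile curve —
  an S-shaped rank plot — spanning `dynamic_orders` = 6 orders of magnitude,
  with 0.15 log10 units of replicate noise. The planted housekeeping block
  (300 proteins) is placed uniformly within the top 0.8 orders so it lands in
  every line's top decile.
* **Expression:** log2 ratio = per-feature baseline (SD 0.5) + per-(feature,
  line) effect (SD 0.8) + replicate noise (SD 0.3). The broad line effects
  reflect that distinct cell lines genuinely differ in much of their
  proteome; they are what makes the BH step-up lenient enough for planted
  effects to be recoverable at n = 3, as in real data. Planted differential
  blocks **replace** the random line effects on their rows so their contrasts
  are exact: per-line blocks ±2.0 log2 in one cancer line, common blocks ±2.0
  in all three cancer lines, CR-vs-CS blocks ±1.0 on each side (total
  separation 2.0 log2 ≈ 2 SD of the normalized expression distribution).
* **Truth:** because a planted shift in one contrast can imply truth in
  another (a CS-only downshift is a genuine resistance marker), effective
  truth sets are derived from the noiseless signal's group means, alongside
  the raw planted block memberships; recovery is scored as precision/FDR
  against effective truth and recall against the planted core.
* **Missingness:** dropout probability is logistic in log10 abundance
  (missing-not-at-random, like intensity-dependent MS detection) plus a 5%
  uniform component; phosphosites inherit their parent's abundance with an
  extra detection penalty. Parameters are set so that roughly 40% of
  proteins and 35% of sites survive the all-lines valid-value filter.
  Planted analysis blocks are protected from dropout; presence/absence
  blocks have their missingness forced to satisfy the CR_only/CS_only
  definitions exactly, and a guard restores one valid value in any
  background feature that would satisfy the rule by chance, making the
  planted-block recovery deterministic (precision = recall = 1).
* **Phosphosites** couple to their parent protein's realized log2 values
  with weight 0.3 (the rest is site-specific), which puts the per-line
  protein–phosphorylation correlation near 0.5. One kinase's substrate sites
  get a consistent +1.25 log2 shift in both CR lines (≈ 1.6 SD of the
  consistent-site score distribution). One module's genes share a latent
  per-sample factor (loading 0.8, residual SD 0.6).
* **Seeding:** every block draws from a named substream derived from the one
  seed, so adding or resizing a block does not perturb the other blocks'
  draws, and identical (config, seed) pairs are bit-reproducible.

What the generator does **not** emulate: peptide-level inference, ratio
compression, correlated replicate batch effects, shared complex-level
covariance among background proteins, or annotation bias in gene sets.
Passing tests therefore certify the pipeline's statistical machinery and
rule logic under a faithful but idealized missingness and effect structure,
not performance on any particular real dataset.

## Problem sizes and runtime

The default generator (3200 proteins, 3700 sites) runs the full pipeline in
a few seconds. Monte-Carlo tests use deliberately scaled problem sizes — 100
seeded generator runs for the kinase-rank property use a 400-protein
configuration with the same block structure, the overdispersion-calibration
test uses 200 random sets × 199 permutations on a 100-gene null matrix, the
type-I calibration 5000 null features × 20 seeds — chosen so the entire
suite stays in the low minutes on one CPU while keeping each check's
Monte-Carlo error well below the margins being asserted.

## Known limitations

* The pairwise-complete distance rescaling in clustering is one defensible
  choice among several; it is recorded in the dendrogram metadata and only
  matters when missingness differs strongly between sample pairs.
* Per-sample z-scoring assumes the lines have comparable expression
  dispersion; a line with systematically lower dispersion would have its
  contrasts slightly inflated after normalization.
* The hypergeometric test treats genes as exchangeable; no gene-length or
  abundance bias correction is attempted.
* Protein groups are collapsed to their first gene symbol for annotation and
  network purposes; multi-gene groups are therefore represented by one
  symbol (logged).
* With missing-not-at-random dropout the realized abundance span of
  *identified* proteins is slightly below the generative 6 orders (the
  faintest proteins are never observed), typically 4.9–5.8 orders.
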