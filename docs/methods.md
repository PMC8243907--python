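# Methods

## Data model and transforms

The pipeline's primary object is a probe × sample matrix of beta values
(methylation fractions in [0, 1]). Statistical work happens on M
values, m = log2((β + ε)/(1 − β + ε)); the offset ε (default 0.01,
configurable) keeps fully (un)methylated probes finite. The transform
is strictly increasing and antisymmetric about β = 0.5, and exactly
invertible for any ε. Beta-scale effect sizes are reported alongside
M-scale statistics because beta differences are what practitioners
interpret.

Genomic coordinates are 1-based and fully closed, matching
array-manifest convention. A probe's regulatory class relative to a
gene is assigned with sub-interval precedence (promoter, then UTR, then
gene body); failing those, it is *upstream* iff it lies strictly
upstream of the TSS by at most 1,500 bp on the gene's strand, else
intergenic. A probe on another chromosome is intergenic, never an
error; the assignment is a total function.

Missing beta values are handled at read time: probes missing in more
than half the samples are dropped (logged), the rest are imputed with
the probe-wise median — deterministic and independent of sample order.

## Synthetic cohorts

No public multi-region methylation cohort with per-sample anatomy fits
this design, so validation runs on simulated cohorts with planted
truth. The generator models:

- **Baseline methylation**: a bimodal Beta mixture (55% Beta(1.5, 8),
  45% Beta(8, 1.5)), the classic two-hump array histogram.
- **Clonal drift**: a rooted clone tree; a fixed 5% subset of probes
  ("drift probes", shared across edges so clones separate on a sparse
  signature) receives an M-space shift ~ N(0, σ²_drift · L) per edge of
  length L, inherited by descendants. Drift acts in M space and is
  mapped back to beta, so values stay in [0, 1] without truncation
  artifacts. Default σ_drift = 2.0 M units per unit edge length.
- **Technical noise**: per-sample N(0, σ²_noise) in M space, default
  σ_noise = 0.3 — small against drift but large enough that planted
  structure is not trivially recoverable.
- **Stromal admixture**: observed beta is a convex mixture of the tumor
  profile (weight = purity, default 0.7) and per-cell-type reference
  profiles (endothelial, fibroblast, immune), with per-sample Dirichlet
  jitter around clone-specific stromal weights. Signature probes are
  excluded from drift so the deconvolution reference stays
  clone-invariant. The default design tilts immune admixture up in the
  C2-analog clone and fibroblast up in the C3 analog.
- **Copy number**: clone-specific segments shift only the parallel
  log2-intensity matrix (per-probe noise SD 0.1); methylation and copy
  number are treated as parallel read-outs of the same clones.
- **MGMT promoter**: a 10-probe promoter block of a designated MGMT
  gene; promoter betas are drawn once per methylation *state*
  (methylated ~ Beta(8, 2), unmethylated ~ Beta(2, 8)) so the state is
  heritable and degenerate configurations (no drift, no noise, full
  purity) reproduce exactly identical samples. Stromal profiles at
  these probes are kept low-beta, as in non-neoplastic brain.

The default cohort is nine samples in three clones — {s1},
{s2, s3, s4, s9}, {s5…s8} — at 50,000 probes on four synthetic
chromosomes (a desk-scale stand-in for an 850k-probe array), with
anatomical coordinates for each site and sample s1 flagged as the
primary resection. Everything above is configurable; identical config
and seed give byte-identical output.

**What the simulation does not model**: probe cross-reactivity,
SNP-affected probes, batch effects, bisulfite-conversion failure,
purity/ploidy interaction with intensity, or realistic gene/CpG-island
geometry. Passing recovery tests on these cohorts demonstrates that the
pipeline's inference machinery is correct under its own generative
assumptions — not that those assumptions capture any particular
patient. No quantitative inter-sample methylation distances from real
tumors were available to calibrate the defaults, and the tests make no
such claim.

## Probe selection and clustering

"Most variable" probes are the top k (default 10,000) by across-sample
standard deviation of beta, ties broken lexicographically by probe id
for determinism; median absolute deviation is available as an
alternative criterion. Clustering is agglomerative on sample columns —
default Euclidean distance on M values with Ward linkage; beta-space
and other metrics/linkages are exposed because studies of this kind
rarely state their choice and results should be checkable under
several.

When the cluster count is not fixed, k is chosen over 2…min(6, n − 1)
by the mean **centroid-based (simplified) silhouette**: per sample,
(b − a)/max(a, b) with a = distance to its own cluster centroid, b =
distance to the nearest other centroid. The classic pairwise silhouette
pins every singleton cluster at zero, which makes it structurally
unable to ever prefer a partition that isolates one genuinely distinct
sample — yet a single-sample clone (the primary resection versus later
recurrences) is exactly what a multi-region tumor design expects. The
centroid form lets an isolated sample score well while behaving like
the classic criterion on partitions without singletons; on
well-separated two- and three-group data it picks 2 and 3 respectively.
Fixing `k=3` reproduces the three-group analysis shape directly.

## Phylogeny and spread path

The sample phylogeny is a neighbor-joining tree on the same
sample-by-sample distances (NJ is exact on additive metrics, which the
tests verify up to 8 taxa). Negative NJ branch lengths — an artifact on
non-additive data — are clamped to zero and logged. The tree is rooted
on the midpoint of the pendant edge of the primary sample, following
the narrative that recurrences diverged from the original tumor. The
dendrogram from hierarchical clustering is retained as its own output;
the phylogeny is NJ, not the dendrogram.

The spread path walks the tree outward from the primary-sample leaf
(the degree-2 rooting node is suppressed so branch lengths add), taking
at every node the outgoing edges in order of increasing branch length,
ties by node name. Internal nodes inherit the coordinate centroid of
the leaves beyond them; each step pairs methylation distance with
Euclidean anatomical distance in mm. The path is a hypothesis-shaped
ordering, not an inference of migration routes.

## Differential methylation

Per probe, clusters with ≥ 2 samples each are compared by Welch's t on
M values. When one cluster is a single sample — unavoidable when the
primary resection is its own cluster — that sample is scored as z =
(x − μ)/max(s, s₀) against the other cluster's probe-wise mean and SD,
with the SD floor s₀ = 0.1 M units preventing degenerate certainty;
the `method` column flags which statistic produced each row. Two-sided
p values get Benjamini–Hochberg correction across all tested probes;
the significant set is q < 0.01. Effect sizes (`delta_beta`) are always
mean beta differences.

Gene summaries use only probes whose region class links them to a gene
(gene body, promoter, UTR, upstream). A gene's score is the mean delta
beta over its *significant* probes; genes with none are excluded, not
scored zero. Top-50 lists per direction are ranked by |score| with
ties broken by symbol; three-way Venn region counts are exact set
cardinalities.

## Copy number

Log2 intensity ratios are median-centered per sample (gains and losses
are relative to each sample's own baseline), then binned 50
position-consecutive probes at a time (bin value = median). Recursive
binary segmentation finds, in each interval, the split maximizing the
two-sample t statistic with **interval-pooled variance**; the split is
accepted if its permutation p (within-interval shuffles, ≥ 1,000,
seeded) is below α = 0.01, and accepted splits recurse with at least 3
bins per side. The pooled scale matters: a per-side (Welch) scale is
unstable under permutation of step-like series, where a chance
near-constant short side inflates the null maximum and masks real
breakpoints. Segment means are probe-weighted so they reconstruct the
binned series exactly.

Calls: amplification iff mean log2 ≥ 0.3; gain in [0.1, 0.3); loss at
or below −0.1; else neutral. Only the amplification bound is a
domain-standard constant; the symmetric ±0.1 gain/loss defaults are
this package's choice and configurable. No allele-specific copy number
and no purity/ploidy correction.

## MGMT and deconvolution

MGMT promoter status is the mean beta over a configurable promoter
probe list, methylated iff ≥ 0.35 (boundary inclusive). This
mean-beta threshold is deliberately simple and transparent; a published
two-probe logistic model can be layered on by supplying its probes and
an adjusted threshold. The call is monotone in the threshold.

Cell fractions are estimated per sample by constrained least squares:
minimize ‖S·f − β‖² subject to f ≥ 0, Σf = 1, solved by NNLS on the
signature system augmented with a heavily weighted sum-to-one row and
renormalized exactly. This is a deterministic stand-in with the same
contract (non-negative, sum-to-one fractions over a reference
signature) as ν-SVR-based deconvolution tools, not a reimplementation
of any of them; residuals are reported per sample, exact mixtures are
recovered to numerical precision, and a rank-deficient signature warns
but still solves. Between-cluster comparisons per cell type use
Kruskal–Wallis (exact Mann–Whitney for two clusters when ties permit);
constant columns get p = 1 by convention. No multiplicity correction is
applied by default — mirroring per-cell-type reporting conventions — and
a BH option exists. Because fractions are compositional, an enrichment
planted in one cell type necessarily shifts the complementary types;
per-type p values should be read with that in mind.

## Enrichment

Gene rankings for one cluster comparison are signed mean delta beta
over significant gene-body and promoter probes, hypermethylated genes
at the top. The enrichment score is the weighted KS running sum: set
members add |score|^p normalized over members (p = 1 default; p = 0
reduces to the classic KS statistic), non-members subtract 1/(N − Nh);
ES is the signed maximum deviation, and the leading edge contains the
members at or before a positive maximum (at or after a negative
minimum). A set covering the whole list has ES defined as 0.

Significance uses **gene-label permutation** (re-drawing the member
positions uniformly): with only 1–4 samples per cluster, sample
permutation is degenerate. p = (1 + #{|ES_null| ≥ |ES|})/(n_perm + 1),
bounded below by 1/(n_perm + 1); NES divides ES by the mean |null ES|
of the same set size; BH q across sets. The null is shared across sets
of the same size for efficiency, which correlates their p values
slightly but does not bias any individual one.

## Pipeline and reproducibility

`run_all` executes simulate → select → cluster → phylogeny → path →
dmp → genes → venn → cnv → mgmt → deconv → gsea, halting on the first
failure with the stage named. All outputs are written atomically; the
JSON run report echoes every parameter plus a SHA-256 config hash and
contains no timestamps, so identical config and seed produce a
byte-identical report. Every stochastic stage (simulation, segmentation
permutations, GSEA permutations, silhouette-free stages are
deterministic) is driven by explicit seeds.

Problem sizes used in validation: the default 50,000-probe cohort for
end-to-end, clustering-recovery (20 seeds), CNV-recovery (10 seeds,
one sample per clone) and MGMT checks; 3,000–10,000-probe cohorts for
differential-methylation calibration (5–20 seeds); 200 random gene sets
at 200 permutations for enrichment calibration. These sizes keep the
whole suite to well under a minute per scenario while leaving
Monte-Carlo margins wide relative to the asserted thresholds.

## Known limitations

- The z-vs-cluster statistic for singleton clusters has no finite-sample
  guarantee; its SD floor is a pragmatic regularizer and results for
  single-sample comparisons should be treated as descriptive.
- Recursive binary segmentation with a permutation test is this
  package's choice of segmentation algorithm; it is not circular binary
  segmentation, though it behaves similarly on step-like profiles.
- Automatic k selection with the centroid silhouette can over-split
  when extra singletons score well; in the default validation it
  occasionally returns k = 5 on individual seeds (the modal value over
  seeds is 3). When the expected structure is known, fix k explicitly.
- Deconvolution quality is bounded by the supplied signature; training
  signatures is out of scope.
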