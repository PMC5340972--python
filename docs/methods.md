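# Methods

This note documents the models, statistics and numerical choices behind
`immevo`, and what the synthetic-data generators do and do not emulate.

## Expression model and quality control

Expression is handled in two units: linear TPM (columns sum to 10⁶) and
E = log₂(TPM + 1).  The unit is carried as a tag on the matrix container and
every operation checks it, so a matrix cannot be log-transformed twice or fed
to an operation in the wrong unit.

Cell QC removes cells with fewer than `min_genes` detected genes or fewer
than `min_reads` transcript-mapped reads (defaults 500 and 10,000).  "Detected"
means TPM strictly greater than zero, and both boundaries are strict
("fewer than"), so a cell with exactly 500 genes and 10,000 reads passes.
Whether the read count refers to pairs or mates is a property of the input
counting; the filter itself is agnostic.  The filter is idempotent and never
modifies surviving cells.

Pseudobulk agreement is the Pearson correlation between the cellwise-mean E
profile and a bulk profile on the gene intersection; fewer than three shared
genes or a zero-variance profile is an error, not a NaN.

## Embedding, batch adjustment, clustering

Cell-to-cell dissimilarity is 1 − PCC over all genes.  Classical MDS
(principal coordinates analysis) double-centers the squared dissimilarities,
B = −½ J D² J, and embeds with the top eigenvectors scaled by the square
roots of their eigenvalues; axes with negative eigenvalues are zeroed.  On an
exactly Euclidean input the embedding reproduces all pairwise distances to
1e−8 (tested).

Batch adjustment is a parametric empirical-Bayes location–scale model:
per-gene batch means and variances, estimated on data standardized by the
pooled residual variance, are shrunk toward a normal (location) and
inverse-gamma (scale) prior with method-of-moments hyperparameters, solved by
the standard fixed-point iteration, then removed.  Two guards matter
numerically: genes with zero total variance pass through unchanged, and when
the across-gene moments are degenerate (the noise-free limit) the per-batch
estimates are used directly, which removes a pure per-gene shift exactly.
Negative adjusted values can optionally be clamped to zero (needed by
methods that require nonnegative input).

Clustering is Ward's criterion in its D2 form (on Euclidean distances, as in
`hclust(..., method="Ward.D2")`) applied to the first four principal
coordinates.  Four coordinates reflect the eigenvalue spectrum of the
embedding, which decays smoothly beyond the fourth component; the count is a
flag.  For each candidate k (default 2–8, truncated with a warning when there
are fewer cells) the dendrogram is cut and the mean silhouette computed in
the same coordinate space as the clustering — the paper-level choice of
silhouette space was open, and consistency with the clustering input is the
design reason.  The smallest k wins silhouette ties.  Cluster labels are
renumbered so cluster 1 is the largest, matching the convention of naming
the dominant (T) population first.

## Cell typing and differential expression

Marker panels score each cell by the mean E over the panel's genes present
in the matrix (family entries like `nitr*` expand by prefix).  A cell is
assigned the unique panel with score strictly above 1; zero or several
panels above threshold leave it unassigned.  Binary "expresses gene X"
display calls use a 5 TPM threshold.

Differential expression between a cluster and the rest uses a dropout-aware
two-part statistic rather than a full Bayesian error model: a Fisher exact
test on detection rates and a rank-sum test on positive E values, each
converted to a signed z, combined with equal Stouffer weights (a missing
part is skipped).  The log₂ fold-change uses group-mean TPM with a
pseudocount of 1.  Multiplicity control is Holm on the two-sided p, mapped
back to the z scale, which guarantees |z_adj| ≤ |z|.  The statistic is
label-symmetric: swapping groups negates both fold-change and z.  The
replacement is deliberate — downstream logic depends only on (log₂FC,
adjusted z), and the thresholds (FC > 2, adjusted z > 3, both strict) are
kept; there is no analogue of a randomization count in this statistic.

Extended signatures keep genes passing both thresholds, ranked by
fold-change; genes qualifying for two or more types are dropped from all so
signatures stay disjoint.  Signature scores are per-cell means over
signature genes, min–max standardized to [0, 1] per signature (all-equal raw
scores standardize to 0).  Cross-species enrichment is a two-sided Fisher
exact test on (DE vs background) × (ortholog-in-signature vs not); SSC
contrasts report (median_a/median_b − 1)·100 with exact rank-sum p for small
samples and the tie-corrected normal approximation otherwise, including
one-vs-rest comparisons.

## V(D)J detection

The reference is every V×J combination as 20 N + V + 7 N + J + 50 N,
standing in for the unknown leader, a possible D segment and the constant
region.  Detection per cell proceeds in four stages:

1. **Recruitment** — a read pair is recruited when either mate shares an
   exact k-mer (default k = 25, either strand) with any germline segment;
   N positions carry no information.
2. **Assembly** — greedy suffix–prefix overlap-layout-consensus: repeatedly
   merge the pair of sequences with the longest exact overlap ≥ 31 nt, all
   relative orientations considered, ties broken by the lexicographically
   smallest merged string; contigs supported by fewer than 2 reads are
   dropped.  Exact-overlap merging is brittle under sequencing errors, so at
   deep coverage (median canonical k-mer count ≥ 10 over read windows) a
   spectrum pass first excises k-mers seen once and splits reads into solid
   pieces ≥ 32 nt; shallow read sets pass through untouched.
3. **Annotation** — affine Smith–Waterman (match +1, mismatch −2, gap open
   −4, gap extend −1) of the contig against every V and J on both strands;
   the best V hit fixes the strand, the junction is the contig span between
   the V end and the J start.  A second (V, J) naming within 5% of the best
   score marks the call ambiguous (counted non-passing), implementing
   "unambiguous" detection.
4. **Filtering** — pass requires both hits present, ≥ 90% identity over
   aligned columns, ≥ 90% of each germline segment recovered, contig-side
   aligned span ≥ 90% of the germline length per hit, and no stop codon in
   the frame propagated from the V segment's annotated offset from V through
   J — a junction-induced frameshift therefore surfaces as a downstream stop
   and fails the call.  Every violated criterion is recorded as a reason.

Association of V(D)J positivity with cluster membership and with *trbc1*
expression (> 5 TPM) uses two-sided Fisher exact tests; degenerate margins
report p = 1 with a flag.

## Conservation statistics

Bulk signatures: genes are prefiltered by maximum group mean (5 for
mouse-style arrays, 8 for human), subtypes merged (CD4/CD8 → T,
monocyte/granulocyte → myeloid), each group tested against the rest with a
moderated t — per-gene variances shrunk toward a scaled-inverse-chi-square
prior whose df and scale come from method-of-moments on log s² (trigamma
inverse by Newton iteration); `prior_df=0` recovers the ordinary pooled t
exactly (tested).  BH-adjusted p < 0.01, ranked by fold-change, top 100
unique per type.

Ortholog proportions compare gene sets per species; the permutation null
shuffles set-membership labels over the pooled genes (within a localization
class when sets are class-homogeneous, which is how the pipeline calls it)
and the two-sided p uses the add-one estimator (1 + #{|null| ≥ |obs|}) /
(1 + n_perm), so a saturated test reports 1/(n_perm+1), never zero.  Global
consistency across species uses the paired Wilcoxon signed-rank test, exact
(sign-assignment DP; tied magnitudes handled by doubling midranks) up to
n = 15.  Sequence identity (mean over multiple orthologs) and one-to-one
dN/dS comparisons are two-sided rank-sum tests on conserved genes only, with
missing rows excluded and counted.

Cluster-level gene sets for conservation take the top 100 DE genes with
z > 1 (strict), sorted by fold-change with a deterministic gene-id
tie-break.  The expression-matched background contains the non-DE genes at
or above the global mean of per-gene mean E, recomputed on the input matrix
(≈ 0.46 on the emulated study's scale) — lowly expressed genes are excluded
because conservation correlates with expression level.

## Paralog divergence

Duplication age is read from the duplication-node taxon: Actinopterygii,
Neopterygii, Otophysa, Clupeocephala or Danio rerio → recent; Euteleostomi,
Bilateria, Chordata or Vertebrata → early; anything else is an error.  Genes
in both age classes are excluded from both.  A gene is detected when TPM > 0
in at least ⌈1% of cells⌉.  Pattern labels follow the precedence
specific > depleted > ubiquitous (detected in ≥ 10% of the cells of every
cluster) > none; within a tier the lowest cluster index wins.  Pair rules:
any "none" excludes the pair (counts reported); both-ubiquitous pairs are
excluded; ubiquitous + other is kept (as diverged) only when the other gene
is specific to or depleted from a major cluster (C1/C2).  The
neofunctionalization rate is diverged / (diverged + conserved) per age
class.

## Synthetic data: what it emulates, and what it does not

Counts are negative-binomial via gamma–Poisson mixing (variance
μ + φμ², φ = 0.4), with lognormal library sizes (mean 50,000, sd 10,000
mapped reads) and TPM derived from counts and fixed per-gene effective
lengths (uniform 500–3000 nt) — an emulation of RSEM-style quantification,
not a reproduction.  Dropout is logistic in log₂(1 + mean expression)
(midpoint 1.0, slope 1.0); a −∞ midpoint disables it.  Batch effects are
per-gene normal log₂ shifts (sd 0.4) over 2 batches.  Three populations at
(0.65, 0.31, 0.04) of 300 cells are allocated by largest remainder (ties to
the earlier index).  Each population has 30 strongly elevated marker genes
(near-silent elsewhere) and 150 moderately elevated (4×) program genes —
markers drive the score>1 rule, programs give the whole-transcriptome
correlation structure that real cell types have.  SSC values are normal
around per-type locations (100, 125, 330; sd 12), reproducing the +25% and
+203% median contrasts.

Read sets: each recombination-positive cell carries one transcript
leader + V + junction + J + constant (leader 20 nt, constant 50 nt shared
across cells, mirroring the reference pads); the junction is 0–10 uniform
non-templated bases, resampled so the V-frame is stop-free (productive
rearrangement; a stop at a zero-length junction boundary triggers a length
redraw, a negligible deviation from uniformity).  Germline V segments are
stop-free in their own frame and J segments in all three frames so a
productive recombinant always exists; all segments are kept below 90%
pairwise local-alignment identity.  Reads are drawn uniformly with
independent mate positions and per-base substitution errors.

Not emulated: realistic decoy transcript sequence content, alpha/gamma/delta
loci, indel sequencing errors, paired-end fragment-length structure,
ambient-RNA contamination, doublets, and FCS-file structure (SSC is a
numeric column).  Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated noise model, not performance
on real libraries.

Annotation tables plant per-set, per-species ortholog proportions
(Bernoulli), identities (normal, truncated to [0, 100], present only with an
ortholog) and dN/dS (normal, truncated at 0).  Paralog tables plant 37
recent and 129 early pairs with divergence probabilities 0.62 and 0.94 and
taxa drawn from the controlled vocabularies.

## Problem sizes and determinism

Default analyses run at 300 cells × 2000 genes; the V(D)J panel uses 60
cells with 4 V × 3 J toy segments, 50 recombinant read pairs and 100
background pairs per cell; permutation tests use 10,000 permutations (200
per replicate in the 500-replicate calibration check, with 100-gene sets —
one signature's worth).  These sizes keep the full test suite and the
acceptance script to a few minutes on one CPU while leaving every planted
effect well above its detection threshold.  All generators and the pipeline
derive their randomness from a single seed through named `SeedSequence`
substreams; fixed seed means byte-identical outputs.

## Known limitations

* The two-part DE statistic is not a Bayesian error model; its z-scores are
  not numerically comparable to SCDE-style adjusted z, only threshold-wise.
* The greedy assembler targets one dominant transcript per cell; it is not a
  general-purpose assembler and will not resolve two co-expressed
  recombinants sharing a V or J.
* The exact rank-sum path requires tie-free data (ties fall back to the
  corrected normal approximation); the signed-rank path handles ties exactly.
* Classical MDS stores a dense n × n matrix; the implementation is meant for
  hundreds to a few thousand cells, not atlas-scale data.
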