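# Methods

## Problem and model

`methylselect` links probe-level DNA methylation (Illumina 450K beta
values in [0, 1]) to per-gene expression by treating probe choice as
supervised feature selection. For each gene the candidate features are the
probes annotated to it in the manifest; the response is the gene's
discretized expression; the selected probe subset is whatever a wrapped
classifier can best exploit under cross-validation. The approach is
deliberately annotation-agnostic: no probe is privileged by CpG-island
status or genomic position, so gene-body and promoter probes compete on
predictive value alone.

Assumptions worth stating explicitly:

* expression is adequately summarized by a binary up/down state after
  baseline removal — genes whose dysregulation is continuous but small are
  discarded by the thresholding, not modeled;
* samples are exchangeable (no batch or lineage structure) — normalization
  and batch correction are assumed done upstream;
* probes annotated to several genes are candidates for every one of those
  genes independently.

## Discretization

Per sample the expression ratio r is formed on the linear scale (log2 /
log10 inputs are exponentiated first). In `paired_ratio` mode the value
itself is the treated/untreated ratio; in `median_reference` mode r =
value / per-gene median across samples, which requires positive values and
at least a handful of samples for the median to be stable. Labels are
up if r ≥ t, down if r ≤ 1/t, baseline otherwise; baseline samples are
dropped. The reciprocal down-cut (1/t rather than −t on a log scale) makes
the rule invariant to inverting the ratio direction: replacing every r by
1/r exactly swaps up and down.

Defaults: t = 1.1 for paired designs, t = 1.2 for median-referenced
cohorts (the larger threshold absorbs the extra noise of unpaired tissue
data). A gene enters selection only if it retains ≥ 10 labeled samples
with ≥ 2 per class — below that a 10-fold CV stops being meaningful —
and skipped genes are logged with the reason.

## Sequential forward selection

The wrapper scores a probe set by the mean per-fold misclassification
count, mean(O), in a stratified 10-fold CV (folds are reduced to the
sample count when fewer than 10 samples remain). Fold assignment deals
each class round-robin after a seeded shuffle, so per-fold class counts
differ by at most one; the same assignment is reused for every candidate
evaluation within a gene, making all comparisons paired. Selection starts
from the best single probe and accepts a further probe only on *strict*
improvement; equal error with more probes stops the search, keeping the
smaller set. Argmin ties go to the lowest candidate index. The stored
`final_cv_error` is the equivalent fraction of samples (mean(O) ·
n_folds / n), which is scale-free across genes with different sample
counts.

## Classifiers

* **KNN** (K = 1, 3, 5; Euclidean). Implemented directly so the tie rules
  are part of the contract: training rows are canonicalized by sample id,
  neighbor order is a stable sort on (distance, sample id), and an even
  vote — possible only through distance ties — falls back to the single
  nearest neighbor. Predictions are therefore invariant to the order
  training samples are presented.
* **Decision tree**: Gini impurity, axis-aligned best-first splits, a node
  is splittable at ≥ 10 observations and leaves may hold 1 (scikit-learn
  `DecisionTreeClassifier` behind the module surface).
* **Naive Bayes** with per-feature Gaussian kernel densities; bandwidths
  follow Silverman's rule floored at 1e-3 beta units so constant features
  yield a proper (if narrow) density instead of a crash.
* **SVM**: linear kernel, C = 1 (scikit-learn `SVC`). A single-class
  training fold raises a degenerate-training error; CV and LOO harnesses
  catch it and fall back to majority-of-training prediction for that fold,
  logging the event.

## Comparison selectors

* **SVM-RFE** uses a Gaussian-kernel SVM with class weights solving
  n₀·w₀ = n₁·w₁ (w₁ = 1, w₀ = n₁/n₀, kept as exact rationals), so
  misclassifying the minority class costs more. Features are scored by the
  change in the fitted dual objective when the feature is removed from the
  RBF kernel with the alphas held fixed; the lowest-scoring feature is
  eliminated each pass and the ranking is the reverse elimination order.
  Score ties (e.g. duplicated probes) eliminate the larger candidate index
  first. The correlation-bias-reduction variant of kernel RFE is out of
  scope.
* **ReliefF** visits every sample once in a seeded order; for each visit
  the k nearest same-class hits and other-class misses (Euclidean over all
  candidates) update each weight by −mean((x−h)²) + mean((x−m)²), with
  1/m normalization over the m visits. k = 1 reduces to the classic
  single-neighbor update. Classes smaller than k reduce k with a warning.
* **GA-KNN** evolves binary probe masks minimizing
  resubLoss / (N − S) — the resubstitution loss of a KNN on the selected
  probes over a denominator that shrinks as more probes are selected,
  penalizing large S. Masks with S = 0 or S = N get +∞. Defaults:
  population 50, 100 generations, per-bit mutation 1/N, crossover 0.8,
  elitism 2, tournament size 3. Note the K = 1 degeneracy: 1NN
  resubstitution loss is identically 0 whenever no two identical feature
  vectors disagree, so with K = 1 the fitness is 0 for every admissible
  mask and the search cannot distinguish them; the implementation follows
  the stated objective and documents rather than repairs this.
* **Controls**: a size-matched uniform random draw of probes, and the two
  probes with the largest |Pearson correlation| between beta values and
  continuous expression over the labeled samples (constant probes score
  0). The random, ReliefF and SVM-RFE selection sizes are matched per gene
  to an SFS reference run, mirroring the benchmark design.
* **Annotation-based**: all probes; island probes in upstream groups
  (TSS200, TSS1500, 5'UTR, 1st exon); probes within ±2500 bp of the TSS
  (boundary inclusive); the single highest-SD probe (ties to the lower
  candidate index).

## Evaluation

Leave-one-out CV with down-expressed samples as positives. The classifier
is paired to the selector: SFS selections are evaluated with the
classifier that drove the selection, GA-KNN/ReliefF and the controls with
KNN, SVM-RFE with the linear SVM, and annotation-based selections with
whatever classifier the caller configures. Accuracy, precision, recall
and specificity follow the usual 2×2 definitions; ratios with a zero
denominator are reported as NaN and excluded from summary means rather
than coerced to 0. MCC uses the zero-denominator → 0 convention so
per-gene means stay defined. Stratification uses strict inequalities
(MCC > 0.6, MCC < 0.2) and the overlap of two gene lists is tested with
the exact hypergeometric upper tail.

## Synthetic benchmark

The generator emulates the *structure* of a 450K study — a manifest with
region groups and island relations at fixed proportions, a probes ×
samples beta matrix, an expression matrix whose discretization reproduces
the planted labels exactly — with a planted signal: per gene, a chosen
number of informative probes draw from truncated normals on [0, 1] with
class-conditional means (defaults 0.2 down / 0.8 up, sd 0.05) while noise
probes draw label-independent Beta(2, 2) values. Expression ratios sit at
1.5·t (up) and 1/(1.5·t) (down), safely beyond the threshold. An optional
label-flip probability decouples expression labels from the methylation
signal to create intermediate-MCC genes. Defaults: 200 genes, 10 probes
per gene (1 informative), 25 samples, balanced classes; a (5, 30) uniform
probe-count range is available to approximate the array's ~18 probes per
gene.

What the generator does **not** emulate: probe–probe spatial correlation
along the genome, beta-value compression near 0/1 from array chemistry,
copy-number confounding, batch structure, or continuous expression noise.
Passing benchmarks therefore demonstrate correctness of the machinery and
recoverability of a planted univariate signal — not performance on real
cohorts. One visible consequence: with the default noiseless effect, every
expression-aware selector that includes the planted probe attains LOO
MCC 1.0, so the top-two-correlated control ties SFS on this benchmark even
though it performs far worse on real data, while the size-matched random
control stays near the 10 % chance recovery rate with mean MCC ≈ 0.

## Numerical and design choices

* Argmin ties everywhere resolve to the lowest candidate index; KNN
  distance ties to the smallest sample id; NB class-score ties to the
  first class in sorted order. All tie rules are deterministic functions
  of ids, never of input order.
* Per-gene seeds derive from crc32(global_seed, gene_id) (< 2³¹), so
  results are independent of gene iteration order and identical between
  serial and any parallel execution.
* Matrices are written with 17 significant digits and read with
  round-trip float parsing, so write → read is bit-exact.
* Manifest dialect: semicolon-separated gene and region cells are paired
  positionally; a gene repeated within one probe keeps its first-listed
  region (warning logged); multi-gene probes join every listed gene's
  candidate set.
* Sample alignment between matrices is the id intersection in methylation
  order; non-overlapping samples are dropped with a warning.
* The SVM box constraint (C = 1), the tree split criterion (Gini) and the
  NB bandwidth floor are configuration defaults, not claims about any
  reference implementation.

## Known limitations

* Binary labels discard effect-size information; genes with many baseline
  samples may fail the usability filter.
* Greedy forward selection is myopic: probe pairs that are informative
  only jointly can be missed after a misleading first pick.
* The GA-KNN objective is degenerate at K = 1 (see above).
* SVM-RFE cost grows roughly quadratically in the candidate count per
  elimination pass; genes with very many probes are slow relative to SFS.
* LOO evaluation reuses the data that drove the selection, so per-gene
  metrics are optimistically biased relative to an external validation
  cohort; between-method comparisons on identical data remain fair.
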