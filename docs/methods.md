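# Methods

## Data model and preprocessing

Input is a row-aligned pair of nonnegative integer count matrices
(cells × genes, cells × peaks) with gene annotations (chromosome, TSS,
strand), peak intervals (BED, 0-based half-open) and optional cell
metadata (type, pseudotime). Preprocessing order is fixed: features
present in fewer than ⌈0.05·N⌉ cells are dropped, sex-chromosome
features removed, each cell scaled to 10,000 total counts and
log1p-transformed, then up to 2,000 highly variable genes selected by
mean-binned normalized dispersion (20 bins on the log1p mean of the
expm1-scale per-gene mean; dispersions z-scored within bins; ties break
to the lower gene index). All-zero cells are retained with a warning
rather than dropped — there is no cell filter in this pipeline.
Accessibility values are kept as normalized counts, not binarized.
GTF input is converted to 0-based coordinates on read; the TSS of a
'−' gene is its interval end − 1. Boundary comparisons on genomic
distances are inclusive (a pair exactly at the 1.2-Mb window edge is a
candidate; a TSS exactly 1 kb from a bait fragment matches).

## Encoders and contrastive pretraining

Two asymmetric encoder pairs (one per modality) produce four cell
embeddings. The teacher treats each feature as a token whose hidden
vector is count × embedding-table row; a one-hidden-layer tanh MLP
scores each token, a learned context vector converts scores to scalar
attention via softmax over the cell's *nonzero* tokens, and the
attention-weighted sum passes batchnorm → dropout → ReLU dense to d
dimensions. The student applies batchnorm → dropout → ReLU dense
directly to the dense count vector. Defaults: d = 128, dropout 0.1,
Glorot-uniform dense/embedding init, context vector ~ N(0, 1/d),
separate context vectors per modality (sharing available by flag).

The NT-Xent loss uses the interleaved 2N index convention documented in
`attune.pretrain`; the denominator follows the published formula
literally, so the positive's self-similarity term appears (for N = 1
identical unit pairs the loss is exactly log 2 — frozen in the tests
against a brute-force oracle). Training: Adam, 20 epochs, batch 32,
temperature 0.1, learning rate decaying exponentially from 1e-4 to 1e-6
across epochs, epoch-level shuffling from the run seed, last incomplete
batch kept. The default pairing contrasts teacher-RNA↔teacher-ATAC and
student-RNA↔student-ATAC; crossed and within-modality pairings are
available as ablation variants.

Because every token hidden is count × table-row, the attention algebra
factors: the tanh-MLP input is count·(E·W_a)[f] and the aggregate is
(attention ⊙ counts) @ E, so no (N × F × d) matmul is ever formed. The
same factorization drives all decoder CLS-row attention (below); a test
verifies it against the materialized attention computation.

## Interaction decoder

Token sequences are the count-scaled teacher embeddings with a learned
CLS vector prepended (position 0). Gene tokens pass self-attention;
cross-attention from gene queries onto peak tokens adds the genomic
distance mask (−10⁹) before the softmax, so masked pairs receive
weight ≤ 1e−6; CLS rows and columns are never masked. A symmetric
cross-attention pass with peak queries over gene tokens (shared
projections) produces the peak-side CLS attention row. Single head and
a single layer by default (configurable); projections are shared across
modalities (self) and directions (cross).

Training objective = NT-Xent between the two cross-attention CLS
outputs + a binary cross-entropy matching loss whose classifier reads
the gene-side cross CLS output for the true pairing and for one
mismatched in-batch cell per cell (equal positive/negative counts).
Negatives are drawn uniformly from the non-matching in-batch cells —
mismatched cells are overwhelmingly dissimilar, so this realizes the
"randomly selected low-similarity cells" construction; similarity-biased
modes (`low_similarity`, `high_similarity`) are available. Uniform
sampling is the default because biasing toward high-similarity (hard)
negatives empirically stalls the matching loss at chance on desk-scale
data, which leaves the attention uninformative.

Three decoder hyperparameters deserve comment, all set by observing the
matching-loss learning curves:

- **Q/K init gain 4.0.** With count-scaled tokens and d = 128, plain
  Glorot initialization leaves attention logits near zero; softmax
  starts uniform, the CLS output then depends only on the key/value
  cell, the matching task is unsolvable through that pathway, and the
  attention receives almost no gradient. Scaling the Q/K inits to give
  unit-order initial logit spread removes the saddle.
- **CLS-contrastive temperature 1.0.** At the pretraining value of 0.1
  this term's gradients are an order of magnitude larger than the
  matching gradients and monopolize the shared CLS pathway.
- **Learning rate 1e-3** (Adam default), 5 epochs, batch 32. Encoder
  embedding tables are fine-tuned jointly by default (freeze flag
  available).

The global attention matrix is Σ over cells of (peak-side CLS attention
row over genes)ᵀ (gene-side CLS attention row over peaks), computed in
evaluation mode over all cells, CLS row/column dropped, masked pairs
forced to zero. The matching loss is the component that makes this
matrix informative: a matched/mismatched decision is only possible when
the CLS attention varies with the query cell, which pushes attention
toward the cell's salient (program-specific) features rather than a
fixed ranking.

## Modality prediction and chromatin potential

The prediction head is an MLP (d → 1000, ReLU → G) minimizing MSE
between predicted and measured log-normalized expression, trained with
Adam (lr 1e-3, 40 epochs, batch 32) on the frozen student-ATAC
embeddings; `from_scratch=True` replaces them with a freshly
initialized untrained student (the de-novo ablation). Freezing keeps
the ablation a clean contrast and avoids overfitting the 600-cell
training sets (joint fine-tuning was tried and degraded held-out RMSE).
The prediction target is normalized log expression, consistent with the
residual definition.

Residual = predicted − measured (both normalized). Per-gene residual
trends along pseudotime use a GCV-penalized smoothing spline
(`scipy.interpolate.make_smoothing_spline`) after collapsing duplicate
pseudotimes to their mean; interior extrema come from a plateau-aware
relative-extremum scan (a strict scan misses symmetric two-point
plateaus); genes are flagged when their residual s.d. exceeds the 0.90
quantile across genes (configurable). Fewer than 10 cells or 4 distinct
pseudotimes → refuse to smooth.

## Metrics

Euclidean distances, k = 30 neighbors by default, self excluded.
FOSCTTM counts strictly closer (< the true-match distance) cells,
averaged over both directions. MAP is the mean average precision of
same-type neighbors within k (cells with no same-type neighbor score
0). Cell-type ASW = (mean silhouette + 1)/2; batch ASW = mean over cell
types of mean(1 − |silhouette on modality labels|) within the type.
Neighbor consistency is the mean Jaccard overlap of kNN sets before vs
after integration, averaged over modalities. The alignment score
subsamples modalities to equal size and computes
1 − (x̄ − k/M)/(k − k/M), clipped to [0, 1]. Graph connectivity averages
the largest-connected-component fraction of each type-restricted kNN
graph. Composites: biology = mean(scaled MAP, cell-type ASW, NC),
mixing = mean(scaled SAS, batch ASW, GC), overall = 0.6·bio +
0.4·mixing; min-max scaling applies only across peer methods and is the
identity for a single method. Prediction metrics: global RMSE and the
mean per-gene Pearson/Spearman across cells, constant genes excluded
with a warning.

## Regulatory evaluation

Candidate pairs are all same-chromosome (gene, peak) pairs with
|TSS − peak midpoint| ≤ 1.2 Mb. A promoter-interactome record labels a
candidate positive when the TSS is within 1 kb of the bait interval,
the peak within 1 kb of the same record's other end, and the record's
best score across cell types is ≥ 5; all other candidates are
negatives. Interval gaps are computed between half-open intervals
(touching intervals have gap 0); inputs must share an assembly
(validated by chromosome-name overlap). AUROC uses midrank tie
handling. Top-pair selection: quantile (top ⌈frac·n⌉, ties broken by
(gene_id, peak_id) lexicographic order) or elbow (maximum deviation
from the endpoint chord of the sorted-weight curve — a kneedle
variant). Dense peak-associated genes have ≥ 10 distinct selected
peaks.

## Pseudo-bulk soft clustering and co-occurrence

Cells are sorted by pseudotime and split into 10 near-equal groups
(remainders to the earliest bins — equal-size bins stabilize pseudo-bulk
variance; equal-width is not offered); group means are z-scored per
feature, constant features dropped with a warning. Fuzzy c-means
(Bezdek iteration, tol 1e-6, ≤ 300 iterations) runs over c = 2..20 with
the fuzzifier m estimated from the data by the Schwämmle–Jensen
formula (override flag); the cluster number is the kneedle elbow of the
minimum inter-centroid distance curve, also overridable. Alpha cores
keep members with membership > 0.5.

Cluster-associated genes: mean Spearman correlation between each
cluster peak's pseudo-bulk profile and each gene's, compared against
the same statistic over 50 background peaks per cluster peak matched on
GC × coverage decile bins (focal peak excluded; empty bins widen to the
GC decile and then to all peaks, with warnings); one-sided Wilcoxon
rank-sum per gene, BH-adjusted. Note the test treats cluster peaks as
exchangeable draws; co-linear cluster profiles make it anti-conservative,
so the ranking statistic (mean ρ) is the primary output and the p-value
secondary.

Per-cell modality state: cosine distance between the paired teacher
embeddings, cells flagged above 0.1. Differential expression: one-vs-rest
Wilcoxon per gene per group on log-normalized values, natural-log fold
change of expm1-scale means with pseudocount 1, BH adjustment per
group, significance at p_adj < 0.01 and logFC > 0.25; single-cell
groups skipped with a warning.

## Synthetic data generator

The generator emulates a differentiation trajectory: pseudotime t ~
U(0, 1), cell type = pseudotime tercile (or n_types-tile), one Gaussian
activity program per type (centers (k+½)/K, width 0.6/K). Linked peaks
read their program's activity at t with shared per-cell lognormal noise
(σ = 0.3); their target genes read the *same* noise realization — except
lag genes, which read the program at t − 0.15 with an independent
realization, so their expression cannot be fully explained by the
cell's current accessibility. That shared-vs-independent noise
structure is what makes chromatin potential detectable: the predictor
can recover the shared component from ATAC but not the lag genes'
earlier state. Decoy peaks and unlinked genes carry unstructured
lognormal activity. Counts are Poisson draws from depth-scaled rates
(baseline 0.1; ATAC depth U(1, 2), RNA depth U(2, 4); amplitudes
U(0.8, 1.2)).

Coordinates: each gene owns a 3-Mb locus on one of four autosomes
(first TSS at 1.2 Mb), so neighboring genes' 1.2-Mb windows never
overlap; its linked peaks (2 per linked gene, ⅔ of genes linked) and
round-robin-assigned decoy peaks sit on a 2.5-kb offset grid within
±1.1 Mb of the TSS, guaranteeing every planted link is inside the
attention window and that no two peaks of a locus collide during 1-kb
truth-set matching. The PCHi-C emulator writes one record per planted
link (bait = TSS ± 500 bp, other end = peak ± 200 bp, score ≥ 5 in the
program's cell-type column) plus optional decoy rows (sub-threshold
scores on real anchors, or high scores with baits in gene deserts), so
truth-set reconstruction at fp_rate = 0 is exact.

What the generator does **not** emulate: batch effects, doublets,
read-level sampling, peak co-accessibility beyond program structure,
trans-chromosomal regulation, nonlinear gene–peak dose response, and
realistic genome geometry (real loci overlap; here windows are
disjoint, which makes the link-recovery task cleaner than on real
data). Passing tests therefore demonstrate that the implementation
recovers structure it is designed to represent, not field performance.

## Problem sizes and determinism

The desk preset (600 cells × 300 genes × 600 peaks, 3 types) is the
default study size; the full pipeline runs in minutes on one CPU and
the test suite exercises it for three seeds. All randomness flows
through `numpy.random.default_rng` seeded from a single run seed per
component; identical seeds give bit-identical embeddings, memberships,
and pipeline manifests on the same platform. The softmax primitive
clips shifted logits at −700 before exponentiation (masked entries
would otherwise hit subnormal-exp slow paths); the additive mask
constant is −10⁹.

## Known limitations

- The matching-loss-driven attention signal is measured at desk scale;
  behavior at atlas scale (thousands of features, hundreds of
  thousands of cells) is untested here.
- The numpy autodiff core is single-threaded and keeps whole-batch
  intermediates; it is sized for the desk preset, not for full-genome
  token sequences.
- Batch ASW and graph connectivity implement one concrete reading of
  the scIB formulations; the neighbor-consistency metric is a Jaccard
  instantiation of neighbor retention.
- The de-novo predictor ablation uses a fixed random encoder rather
  than training the encoder jointly from scratch.
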