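# Methods

## Problem and model

`phalife` classifies phage contigs as temperate or virulent from protein
content and gene order. The representation is linguistic: each protein is
replaced by the id of its homology cluster, so a contig becomes an ordered
token sentence, and a bidirectional transformer encoder learns which
protein families co-occur and in what contexts. The biological premise is
that lifestyle is written in protein composition and association —
integrase/excisionase-like families mark temperate phages, and broader
compositional signatures separate the classes even when no single marker
gene is present on a short contig.

### Vocabulary construction

The vocabulary is built from an all-against-all protein similarity search
in the standard 12-column tabular format. Alignments with e-value above a
cutoff (default 1e-5, the conventional significance default) are dropped;
remaining pairs get the undirected weight

    w(u, v) = max over reported directions of -log10(max(e, 1e-200)),

the standard conversion for running MCL on alignment graphs: MCL needs
larger-is-stronger weights, e-values are smaller-is-stronger, and the floor
keeps perfect self-consistent hits (reported as e = 0) finite. Self-hits
contribute their node but no edge.

Markov clustering runs on the column-stochastic matrix with per-node
self-loops equal to the node's maximum incident weight (1.0 for isolated
nodes), inflation 2.0, pruning of entries below 1e-8, tolerance 1e-6 and at
most 100 iterations (non-convergence warns and returns the current
interpretation rather than failing). None of these values is prescribed by
the approach itself; they are the common defaults of MCL protein-family
protocols and are exposed as parameters. Nodes are sorted lexicographically
before matrix construction and all tie-breaks are deterministic, so a
vocabulary build is byte-for-byte reproducible.

Clusters with one member are removed. Survivors are ordered by (descending
size, lexicographically smallest member) and assigned token ids from 5
upward; ids 0-4 are [PAD], [UNK], [CLS], [SEP], [MASK]. [UNK] is this
package's addition: query proteins with no alignment to any cluster
representative keep a placeholder token instead of being dropped, so
sentence length still reflects gene count and position information stays
intact. The cluster-side target of token assignment is the cluster
representative (lexicographically smallest member), the simplest concrete
reading of "align queries against the clusters".

### Sentences

Coordinates are 0-based half-open throughout; gene order along the contig
defines sentence order regardless of strand. A sentence is exactly 300 ids:
[CLS], up to 298 content tokens (longer contigs keep the first 298), [SEP],
then [PAD]. Padding is excluded from attention via a mask derived from the
content length — not part of the original description, but required for
the encoder output at content positions to be independent of padding.

### Encoder

Learnable token and position embedding tables are summed into X. Each of
the n_layers blocks applies, in post-norm order: multi-head self-attention
(scaled dot product, padding masked), dropout, residual add, layer norm;
then a position-wise feed-forward network (two linear layers with ReLU,
inner width 4 x d_model by transformer convention), dropout, residual add,
layer norm. "Normalisation before and after the feed-forward network" is
ambiguous between pre-norm and post-norm conventions; the post-norm
original-transformer reading is implemented. Position embeddings are
learnable, not sinusoidal. Dropout defaults to 0.1 and is disabled at
inference.

Two presets ship: paper scale (d_model 512, 8 layers, 8 heads) and a desk
preset (64, 2, 4) that all tests, examples and the acceptance script train.
Max sentence length is 300 in both.

The forward and backward passes are explicit NumPy; no autograd framework
is involved. Correctness of every gradient path (embeddings, attention,
layer norm, FFN, both heads) is enforced by finite-difference checks at
relative error < 1e-4 on a one-layer micro-model. Training uses Adam at
learning rate 0.001. Batches are cropped to the longest content span in
the batch before the attention stack; masked positions and the [CLS] row
lie inside the span and padding is attention-masked, so the crop is exact,
not an approximation.

### Masked-LM stage

Each genome contributes its full sequence plus 10 uniform-random substrings
for each nominal length (5, 10, 15, 20 kbp); genomes shorter than the
nominal length contribute the whole sequence for that draw, and draws may
overlap (sampling with replacement — overlap is not forbidden anywhere).
With G genomes this yields G x 41 fragments: 3,474 genomes give 142,434.

Masking selects each content token independently with probability 0.05; if
none is selected one content position is forced, so every example has a
target. Masked tokens are always replaced by [MASK] — deliberately simpler
than BERT's 80/10/10 corruption, which the described procedure does not
use. [CLS], [SEP] and [PAD] are never masked. The loss is cross-entropy of
softmax(Y_i W_d) at masked positions.

"10-fold cross-validation" for a self-supervised task is interpreted as
model selection: k train/validation splits, one model per split, return
the parameters with the lowest validation masked-LM loss. The fold count
and epochs are parameters (the epoch count is nowhere stated; the desk
default is 20).

### Fine-tuning stage

The augmentation range (100 bp - 20 kbp) and the total (160,000 = 2
classes x 8 lengths x 10,000) are fixed, but the eight lengths themselves
are not stated anywhere; this package uses {100, 400, 800, 1200, 1800,
5000, 10000, 20000} — the four benchmark-bin boundary lengths plus the four
pretraining lengths — exposed as a config knob. Class balance is exact by
construction at every length.

Cross-validation splits at genome level, stratified by class
(sklearn StratifiedGroupKFold): fragments of one genome never straddle a
split (fragment-level splitting would leak near-identical sequences and
inflate scores), and each training fold keeps the class balance — pilots
showed class-skewed training folds bias the probability calibration at the
fixed 0.5 cutoff even when ranking (AUC) is perfect. The fold with the
best validation AUCROC is returned. A from-scratch arm (same architecture,
no masked-LM initialisation) supports the ablation comparison.

Prediction: p = softmax(Y_0 W_p + b_p); index 0 is temperate repo-wide,
and a contig is called temperate iff p_temperate >= 0.5 (the boundary goes
to temperate, matching the positive-class convention of the metrics).
Contigs with zero called genes are reported "unclassified" with NaN
probabilities rather than being silently dropped.

### Benchmark construction and dedup

The short-fragment benchmark draws 80,000 fragments per length bin
(100-400, 400-800, 800-1200, 1200-1800 bp; 40,000 per class, lengths
uniform in the bin), then removes near-duplicates at sketch similarity
> 0.8. Similarity is an in-package k-mer MinHash sketch (21-mers, 64 hash
slots, deterministic universal hashing mod the Mersenne prime 2^31 - 1 —
never Python's salted `hash`), with LSH banding (8 bands x 8 rows) to
propose candidate pairs and greedy keep-first-seen resolution. This is a
self-contained stand-in with the same threshold semantics as the external
sketching tool used in the original benchmark design; it is not that tool.

### Metrics

Temperate is the positive class: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/total; empty denominators yield NaN rather
than an arbitrary 0. The ROC curve thresholds scores over all unique
values with ties grouped; AUCROC is the trapezoidal area and equals the
Mann-Whitney U statistic over n+ x n-, which the tests verify against an
independent rank-based computation. No ROC-comparison significance test is
implemented — there is no canonical choice — but a clearly labeled seeded
bootstrap CI for an AUC difference is available.

## The synthetic universe

The generator emulates the statistical structure the method assumes, not
phage biology. Protein clusters are seeded by random ancestors
(20 clusters x 6 members by default) with members point-mutated at rate
0.05 per residue; a few singleton proteins appear only as self-hits.
Genomes (60 per class) are mosaics of 15-30 back-translated genes drawn
from a per-class cluster distribution; five marker clusters are enriched
10-fold in temperate genomes. At that enrichment a temperate gene is a
marker with probability 0.77 versus 0.25 for virulent, separating
genome-level marker composition by roughly three standard deviations so
that the optimal classifier on multi-gene fragments is essentially always
right — the planted signal is meant to test *recovery*, so it is
calibrated to be recoverable; at weaker enrichment a few genomes per
hundred are intrinsically ambiguous and cap attainable accuracy. Alignment
tables are synthesized from the ground truth (within-cluster e-values
10^-k with k uniform in [50, 180]; cross-cluster pairs absent), so
vocabulary construction and tokenization run without an aligner.

What passing these tests shows: the pipeline's bookkeeping, determinism
and learning machinery work end to end, and the encoder can extract a
composition-and-context signal of the kind the method presumes. What it
does not show: performance on real phages — real homology is not block
diagonal, real e-values are noisy, gene callers make mistakes, and real
lifestyle signals are far subtler than the planted one. Back-translation
uses one fixed codon per amino acid and no codon-usage model; gene calling
in tests uses the precomputed-proteins path, so ORF-caller fidelity is
never load-bearing.

Fragments are tokenized against the ground-truth gene layout through the
real best-hit assignment path; a gene belongs to a fragment when the
fragment covers at least half of it, emulating a caller recovering
mostly-contained partial ORFs at fragment boundaries.

## Numerical and engineering choices

- All randomness flows through seeded `numpy.random.Generator` instances;
  corpus builders visit genomes in sorted-id order, so equal seeds give
  byte-identical corpora, training curves and predictions.
- Checkpoints are single-file `.npz` archives (float64 tensors plus a JSON
  config block); save -> load -> forward reproduces logits bitwise.
- Softmax subtracts the row max before exponentiation; layer norm uses
  eps = 1e-5; a non-finite value anywhere in the encoder output raises
  immediately rather than letting instability pass silently.
- Best-hit ties break by highest bit score, then smallest token id;
  vocabulary order ties break by smallest member id; MCL attractor sets
  are merged deterministically. Degenerate inputs (empty alignment table,
  all-singleton clusterings, geneless contigs, zero-content sentences)
  have defined, tested behaviour instead of exceptions wherever the result
  is still meaningful.
- Desk-scale problem sizes used by the tests and the acceptance script
  (hundreds of fragments, 2-3 folds, a few epochs) were fixed by pilot
  runs across several generator seeds and chosen as the smallest sizes at
  which the studied effects are stable.

## Known limitations

- The paper-scale preset (512 x 8 x 8) is provided and correct but slow in
  NumPy; serious paper-scale retraining wants an accelerator framework.
- MCL is dense in memory (O(n^2) for n proteins), adequate for desk-scale
  vocabularies; RefSeq-scale clustering needs a sparse implementation.
- The [UNK] policy, representative-based token assignment, post-norm
  ordering and the 8-length augmentation grid are documented choices on
  points the original description leaves open; alternatives are plausible.
- `predict` requires genes: a contig shorter than one ORF is always
  "unclassified" rather than guessed from k-mer composition.
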