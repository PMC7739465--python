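# Methods

## The prediction problem

Automated protein function prediction assigns Gene Ontology (GO) terms to
proteins. GO organizes the terms of each sub-ontology (biological process,
molecular function, cellular component) in a rooted DAG of child→parent
relations, and annotations obey the True Path Rule (TPR): a protein
annotated with a term is implicitly annotated with every ancestor of that
term. Because a protein typically carries several terms, prediction is a
multi-label problem whose output space — thousands of hierarchically
related, heavily imbalanced labels — is the central difficulty.

`gogcn` couples two learned representations of the same width `d`:

* a **term embedding** `H` (|T| × d), produced by a stacked graph
  convolution over a normalized term-correlation matrix, so that a term's
  representation mixes information from its neighbours in the hierarchy;
* a **protein embedding** `Z` (n × d), produced by a multi-kernel 1D CNN
  over the one-hot amino-acid sequence.

The score of protein *i* for term *s* is the dot product
`⟨Z_i, H_s⟩`, passed through a sigmoid; the whole network is trained end
to end with binary cross-entropy against TPR-closed binary labels.

## Data preparation

Annotations are read from GAF 2.x or two-column TSV, closed under
ancestors (TPR), and the terms of one sub-ontology with at least
`min_count` annotated proteins are selected (defaults 25 for CC, 150 for
BP, 25 for MF), ordered most-frequent-first with lexicographic
tie-breaks. Proteins annotated with none of the selected terms are
excluded. Term counts are taken after propagation, so shallow terms
inherit their descendants' annotations.

Sequences are one-hot encoded over 21 channels — the 20 canonical
residues in alphabetical order plus one shared channel for every
non-canonical symbol (X, B, Z, U, O, J, `*`, …) — at a fixed length of
2000 positions: longer sequences keep their first 2000 residues, shorter
ones are zero-padded at the tail.

## Term correlation and information content

For selected terms, the information content is

    IC(t) = 1 − log(1 + |desc(t)|) / log |T|,

with `desc(t)` the selected descendants of `t` including itself. Deep,
specific terms have high IC. The value is independent of the log base and
is deliberately not clamped: a term whose descendants cover the whole
selected set comes out slightly negative (a `clamp_ic`-style flag floors
it at zero). `desc(t)` ranges over the selected set, for consistency with
the `log |T|` normalizer; ranging over the full ontology is the other
defensible reading.

Each direct parent→child pair `(t, s)` within the selected set gets the
weight

    A(t, s) = n_s / n_t + IC(s) / Σ_{s' ∈ ch(t)} IC(s'),

combining the annotation-frequency ratio with the child's share of the
sibling information content; all other entries are zero. Annotation
counts `n_t` are taken from the training partition only, so no held-out
information leaks into the term graph. When the raw IC vector contains
non-positive entries (possible under the unclamped formula) it is shifted
to be positive before computing the sibling shares, since the weights
need positive mass; the reported IC (used by Smin) is the unshifted one.

The graph convolution consumes a normalized matrix. The normalization is
the package's own choice (none is prescribed by the underlying model
description): the standard symmetric renormalization with self-loops,

    Â = D̃^{−1/2} (A + Aᵀ + I) D̃^{−1/2},

where `D̃` is the diagonal degree of `A + Aᵀ + I`. Symmetrizing lets
information flow both up and down the DAG; self-loops preserve each
term's own signal. A row-stochastic variant `D̃^{−1}(A + Aᵀ + I)` is
exposed for testing.

## Network architecture

**Sequence branch.** For each kernel size `h ∈ {8, 16, 24, 32}` a bank of
128 filters slides over the one-hot sequence at stride 1 with valid
padding, giving feature maps of length `k − h + 1`; batch normalization,
a rectifier and global max pooling follow. The four pooled vectors are
concatenated (512 features) and passed through two fully connected layers
(512→256→d), each preceded by dropout. The four kernel sizes probe
short- to long-range sequence context; max pooling makes each filter a
position-independent motif detector.

**Term branch.** Starting from the one-hot identity `H⁰ = I`, each of the
2 GCN layers computes `H^{l+1} = f(Â H^l W^l)` with a rectifier between
layers and a linear final layer; both layers have width `d = 128`. With
`gcn_layers = 0` the term matrix is a free learned parameter — the
CNN-only ablation, which removes all ontology information.

**Defaults and their status.** Kernel sizes (8/16/24/32), the 21-channel
/ 2000-position encoding, and `d = 128` follow the published
architecture. Filters per kernel (128), stride (1), the dense head
(512→256→128), dropout probability (0.5), the GCN depth/width (2 × 128)
and the rectifier activations are not reported there; they are this
package's declared defaults, all configurable through `ModelConfig`.

**Loss.** Binary cross-entropy from logits,
`softplus(ŷ) − y·ŷ` summed over terms and averaged over the proteins of a
batch; the logit form keeps the loss finite for |logits| up to at least
10⁴. Optimization uses Adam (lr 10⁻³ by default), with seeded
initialization, batch order and dropout, so a fit is a deterministic
function of its seed on one device.

The implementation is pure NumPy with explicit forward and backward
passes for every layer; analytic gradients are verified against central
finite differences (≤ 10⁻⁴ relative error) in the test suite.

## Training protocol

Proteins are shuffled with a seeded generator and split 80/20 (⌊0.8·n⌋
train). Early stopping (default patience 5) monitors validation Fmax and,
when it triggers or training ends with a patience set, the
best-validation checkpoint is restored; with patience disabled the final
weights are kept — restoration is defined as part of early stopping, so
an unregularized run keeps what it converged to. Divergence (non-finite
loss) aborts with a diagnostic.

The **Naive baseline** scores every protein with each term's training
annotation frequency — identical rows for all proteins. It anchors the
evaluation: any model that uses the sequence must beat it.

## Evaluation metrics

Term-centric, macro-averaged over selected terms (terms lacking both
classes in the evaluation set are skipped and logged):

* **AUC** — rank-based, ties counted ½ (Mann–Whitney form);
* **AUPRC** — average precision: mean precision at each positive's rank,
  ties broken by descending score then input order, no interpolation;
* **PR50** — precision at the smallest rank cutoff where recall reaches
  50% (first crossing, not interpolated).

Protein-centric, over a threshold grid of {0.00, 0.01, …, 1.00}
(sigmoid probabilities are thresholded, not logits):

* **Fmax** — maximum over θ of `2·p̄·r̄/(p̄+r̄)`, where per-protein
  precision and recall are averaged over m(θ), the proteins with at least
  one score ≥ θ. Averaging recall over m(θ) follows the printed
  definition of the metric; a `cafa_recall` flag switches to the CAFA
  convention of averaging recall over all proteins.
* **Smin** — minimum over θ of `√(ru² + mi²)`, where remaining
  uncertainty `ru` averages the summed IC of true-but-unpredicted terms
  and misinformation `mi` that of predicted-but-untrue terms. Smin is in
  IC units and is the only metric where smaller is better.

Both protein-centric metrics are verified against brute-force
threshold-enumeration oracles to 10⁻¹² on random instances.

## Synthetic benchmark

The generator builds a layered rooted DAG (single root, each deeper node
drawing 1–2 parents from the previous level), assigns each leaf term a
distinct random 5-residue motif, samples each protein's leaf annotations
independently (Bernoulli, p = 0.3 per leaf, resampled so every protein
keeps at least one leaf), closes them under TPR, and implants the owned
motifs at random non-overlapping positions in an otherwise uniform
random sequence. The sequence→function mapping is therefore exact by
construction, giving parameter recovery a clean ceiling; a `motif_noise`
option drops implants with stated probability for harder variants.

What the generator emulates: hierarchy-consistent multi-label
annotations, frequency imbalance between shallow and deep terms, and a
learnable sequence signal. What it does not: real GO topology statistics,
homology/phylogenetic structure between sequences, non-uniform residue
composition, and annotation noise. Passing the desk-scale experiments
therefore demonstrates that the machinery — data preparation, term graph,
network, optimization, metrics — is correct and can recover a planted
signal; it does not certify accuracy on real proteomes.

## Desk-scale study conditions

Two canned experiments (`gogcn.experiments`) run the full pipeline at
sizes chosen for a single CPU:

* **Overfit sanity** — 20 proteins, 10 terms (3 levels), sequences of
  length 100, 200 epochs, batch 8, early stopping off. A correctly wired
  network must memorize this (training-set Fmax ≈ 1).
* **Signal recovery** — 40 terms (3 levels), 300 proteins of length 300,
  motif length 5, 80/20 split; default architecture with dropout 0.1,
  Adam 10⁻³, batch 8, 150 epochs, early stopping off. The trained model's
  held-out macro AUPRC is compared with the Naive baseline.

The small batch size matters: with global max pooling the gradient
touches one window per filter per protein, so discovering shared motifs
is step-hungry, and at 300 proteins the optimizer needs the extra steps
per epoch (30 rather than 8) to let motif features win over per-sequence
memorization before the epoch budget ends. Early stopping is disabled in
both experiments because validation Fmax is flat during the frequency
plateau that precedes motif learning, and a patience rule would stop
there. Light dropout (0.1) is enough regularization at this data size;
the 0.5 default is kept for realistic-scale corpora.

## Numerical choices and degenerate inputs

* Weights use float32 by default (a float64 mode exists for gradient
  checks); Glorot-uniform initialization throughout.
* Batch normalization keeps running statistics (momentum 0.9) for
  deterministic evaluation-mode inference.
* Fmax skips thresholds with no covered proteins or zero
  precision+recall; if every threshold is degenerate it returns NaN with
  a warning rather than a fabricated score.
* AUC/AUPRC/PR50 require both classes / at least one positive; columns
  that fail this are skipped and counted in the report.
* Term selection is inclusive at the threshold; ties in annotation counts
  are broken lexicographically so runs are reproducible.
* The 0.01-step threshold grid follows CAFA practice; "all possible
  thresholds" is realized exactly by passing the sorted unique score set
  as a custom grid.

## Known limitations

* The Â normalization is a design choice, not part of the published
  model; results are mildly sensitive to it.
* The NumPy implementation targets desk-scale corpora (hundreds to a few
  thousand proteins on one CPU); the architecture is the published one,
  but throughput is far below a GPU framework's.
* Per-namespace models only; cross-ontology edges are out of scope.
* The synthetic benchmark's clean motif signal means reported recovery
  numbers are upper bounds on what equally sized real data would give.
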