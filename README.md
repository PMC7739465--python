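# gogcn

Protein function prediction that couples a graph convolutional network
over the Gene Ontology hierarchy with a multi-kernel sequence CNN.

Automated function prediction assigns GO terms to proteins — a
multi-label problem over thousands of hierarchically related, heavily
imbalanced labels. Most sequence-based deep models ignore the GO DAG;
`gogcn` builds it into the classifier. It is aimed at computational
biologists who want a transparent, fully testable reference
implementation of this architecture that runs on a single CPU.

## The model

For a selected term set T (per sub-ontology, terms with at least a
minimum number of annotated proteins after True-Path-Rule propagation):

* **Term branch.** Every direct parent→child pair (t, s) gets the weight

  A(t, s) = n_s / n_t + IC(s) / Σ_{s′ ∈ ch(t)} IC(s′),

  where n_t counts training proteins annotated with t and
  IC(t) = 1 − log(1 + |desc(t)|)/log|T| is the term's information
  content. A stacked graph convolution over the normalized matrix
  Â = D̃^{−1/2}(A + Aᵀ + I)D̃^{−1/2}, starting from the one-hot identity
  H⁰ = I, yields term embeddings H ∈ R^{|T|×d}
  (H^{l+1} = f(Â H^l W^l), d = 128).

* **Sequence branch.** The amino-acid sequence is one-hot encoded
  (2000 × 21; 20 canonical residues plus one unknown channel), convolved
  with filter banks of kernel sizes 8/16/24/32 (128 filters each, valid
  padding, feature length k − h + 1), batch-normalized, rectified and
  global-max-pooled, then mapped 512→256→d by two dropout+dense layers,
  yielding protein embeddings Z ∈ R^{n×d}.

* **Fusion.** Ŷ = Z Hᵀ scores every protein–term pair; sigmoid
  probabilities are trained end to end with binary cross-entropy.

Evaluation follows community practice: macro-averaged per-term AUC,
AUPRC and PR50, plus protein-centric Fmax (best harmonic mean of
averaged precision/recall over a threshold grid) and Smin (minimum
IC-weighted semantic distance). A Naive baseline scoring each term by
its training frequency anchors every comparison. The network is pure
NumPy with explicit backpropagation, verified against finite differences.

## Worked example

```python
import numpy as np
from gogcn import (SynthConfig, generate_dag, generate_proteins,
                   select_terms, build_label_matrix, encode_batch,
                   DeepGOAModel, TrainConfig, ModelConfig)

# a desk-scale benchmark: 12 terms, 30 proteins, motifs implanted so the
# sequence -> function mapping is exactly learnable
cfg = SynthConfig(n_terms=12, n_levels=3, n_proteins=30,
                  seq_length=120, motif_length=5, seed=3)
graph = generate_dag(cfg)
records, annotations, _ = generate_proteins(graph, cfg)
index = select_terms(annotations, graph, "BP", min_count=1)
labels = build_label_matrix(annotations, index)
seqs = dict(records)
_, enc = encode_batch(((p, seqs[p]) for p in labels.proteins),
                      max_len=cfg.seq_length)

model = DeepGOAModel(labels, enc, graph=graph,
                     config=ModelConfig(seq_len=120, kernel_sizes=(4, 6),
                                        filters_per_kernel=16, embed_dim=16,
                                        dense_hidden=32, dropout_p=0.2))
res = model.fit(TrainConfig(max_epochs=5, batch_size=8, seed=0))
print(res.summary())
```

prints

```
Joint CNN+GCN function predictor
================================
proteins: 30 (24 train / 6 validation)
selected terms: 12
embedding width d: 16
kernel sizes: [4, 6] x 16 filters
gcn layers: 2
epochs run: 5 (best: 4)
final train loss: 8.8508
best validation Fmax: 0.6649

Evaluation report
-----------------
proteins: 6   terms: 12 (scored: 11)
macro AUC:   0.5730
macro AUPRC: 0.6426
macro PR50:  0.6625
Fmax: 0.6649 at threshold 0.50
Smin: 2.0831 at threshold 0.53
```

Five epochs on 24 proteins only begin to move the validation metrics —
the result object reports the split sizes, the training trajectory and
the full metric panel on the held-out proteins; `docs/methods.md`
explains why motif learning is step-hungry and which schedules recover
the planted signal (held-out macro AUPRC ≈ 0.73–0.82 on the 300-protein
benchmark, against ≈ 0.43–0.47 for the frequency baseline).

The same pipeline is scriptable from the shell:

```
gogcn simulate --out data/ --n-terms 40 --n-proteins 300
gogcn build --obo data/ontology.obo --fasta data/proteins.fasta \
            --annotations data/annotations.tsv --min-count 1 \
            --max-len 300 --out bundle/
gogcn train --bundle bundle/ --epochs 150 --seed 1 --out model.npz
gogcn predict --checkpoint model.npz --fasta data/proteins.fasta --out pred.tsv
gogcn evaluate --truth truth.tsv --predictions pred.tsv --ic bundle/ic.tsv
```

Real data goes through the same `build` step: an OBO release, a FASTA
file, and GAF 2.x or two-column TSV annotations.

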