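# structok

Joint sequence–structure models for multi-label protein property prediction
— EC/GO-style binary term prediction over protein chains — built around
discrete **structure tokens**.

## The problem and the approach

Protein function prediction is framed as many binary classification tasks:
for each protein chain and each ontology term (an EC class, a GO term),
predict a score in (0, 1). Sequence-only language models miss information
that lives in the 3D backbone; this package couples the two modalities:

1. **Structure tokenization.** Each residue's local structure — the graph of
   the residue and its 10 spatially nearest neighbors by Cα distance, with
   purely geometric node/edge features (no amino-acid identity) — is encoded
   by a geometric vector perceptron (GVP) network whose scalar outputs are
   invariant to rotation and translation. Mean-pooled node embeddings are
   quantized against a k-means codebook of K = 2048 centroids; the centroid
   index is the residue's structure token.
2. **Sequence–structure disentangled attention.** A transformer encoder runs
   over the parallel residue-token and structure-token sequences. The full
   cross attention between content (S), structure (ST) and relative position
   (P) factorizes into 9 bilinear terms; the five retained ones are

   Â(i,j) = Q_s,i·K_s,j + Q_s,i·K_st,j + Q_s,i·K_p,δ(i,j)
          + Q_st,i·K_s,j + Q_p,δ(j,i)·K_s,j,

   with H₀ = softmax(Â/√(5d)) V_s.
3. **Multi-scale residual head.** Parallel 1-D convolutions of widths 3/5/7
   (Conv–BN–GELU–Conv–BN per branch) are summed with an identity shortcut,
   H' = H²₃ + H²₅ + H²₇ + H, stacked, average-pooled over valid residues,
   and classified by a per-task logistic linear layer.

Evaluation uses the CAFA-style protein-centric **Fmax** (maximum F-measure
over a decision-threshold sweep, precision averaged over proteins with at
least one prediction, recall over all proteins) and the pair-centric
**AUPR** (micro-averaged average precision over all protein×term pairs).

A seeded synthetic-protein generator (idealized helical/extended backbones,
planted sequence motifs and geometry-dependent labels) makes every component
trainable and testable on one CPU with no external data. Model selection
follows validation Fmax; test metrics come from the selected checkpoint.

The neural components run on a small numpy autograd engine shipped in
`structok.nn`; PDB/FASTA I/O goes through biotite/Biopython, k-means through
scikit-learn.

## Worked example

```python
from structok import (SyntheticConfig, generate_dataset,
                      StructureTokenizer, SequenceStructureClassifier)
from structok.pipeline import evaluate_split

proteins, labels = generate_dataset(SyntheticConfig(n_proteins=60, seed=42))
tok = StructureTokenizer(n_tokens=32, pretrain_epochs=1, seed=0).fit(proteins)
tokens = tok.transform(proteins)

clf = SequenceStructureClassifier(n_structure_vocab=32, r_max=16, epochs=10, seed=0)
clf.fit(tokens, labels)                      # selects by validation Fmax
result = evaluate_split(clf, tokens, labels, "test")
print("best validation Fmax:", round(clf.best_val_fmax_, 3))
print("test Fmax:", round(result.fmax, 3))
print("test AUPR:", round(result.aupr, 3))
```

Output:

```
best validation Fmax: 0.708
test Fmax: 0.667
test AUPR: 0.66
```

The dataset plants five labels (three sequence motifs of widths 3/5/7, a
helix-content rule and a contact-density rule); after 10 epochs on 48
training proteins the classifier recovers a large part of the signal —
`test Fmax` is the maximum F-measure on the 6 held-out proteins and
`test AUPR` the micro average precision over all held-out protein×term
pairs. Longer budgets (the structure-signal experiment below uses 300
proteins and 40 epochs) reach Fmax ≈ 0.8.

Both estimators follow scikit-learn conventions (`fit`/`transform`/
`predict_proba`, `get_params`); a `structok` CLI exposes the same workflow
as subcommands (`simulate`, `fit-codebook`, `tokenize`, `train`, `predict`,
`evaluate`, `ablate`), each writing a JSON run manifest.

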