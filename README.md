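# freqlink

Frequency-aware graph representation learning for predicting
pseudogene–miRNA associations.

Pseudogenes act as competitive endogenous RNAs (ceRNAs): by binding the
same miRNAs as protein-coding transcripts they couple regulatory
programs, and experimentally validated pseudogene–miRNA pairs are scarce.
`freqlink` treats the known associations as a bipartite graph
G = (V, ξ) with pseudogene nodes P = (p₁…p_N) and miRNA nodes
M = (m₁…m_A), and ranks unobserved pairs by a learned score — for
bioinformaticians who want a self-contained, CPU-only link-prediction
pipeline they can run on any two-column association table.

## Method in brief

1. **Node features**: each sequence becomes its k-mer frequency vector
   (4^k dimensions; 64 at the default k = 3), with T↔U equivalence.
2. **Optimal-frequency pooling** on the symmetric normalized Laplacian
   L = I − D^{−1/2}AD^{−1/2}: a *Rayleigh* branch reweights feature
   channels by their Rayleigh quotients xᵀLx/xᵀx and amplifies the
   high-pass component L·X (H_RQ), while a *Chebyshev* branch applies a
   learnable low-pass polynomial filter Σ θ_k T_k(L̃) (H_CWT). The fused
   node features are π·H_RQ + (1−π)·H_CWT.
3. **Two views per candidate pair (p, m)**: the *enclosing subgraph*
   (alternating k-round expansion with the candidate edge removed) and
   the *random-walk-with-restart* profile ρ = c·AD^{−1}ρ + (1−c)e of the
   pseudogene, truncated to its top miRNAs; the views are merged.
4. **Encoder + scorer**: a two-layer GCN Z = Â·relu(Â·X·W₁)·W₂ on the
   merged view and an MLP on [z_p ‖ z_m], trained with
   (1−α−β)(L_cl + L_kl) + L_bce — a bilinear contrastive loss tying the
   two spectral branches, a KL alignment between the local and global
   views, and binary cross-entropy on the labels.

Evaluation is stratified k-fold cross-validation with uniformly sampled
negatives, with every test positive edge removed from the graph each
fold trains and samples on. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import freqlink as fl
from freqlink.train_eval import RunConfig, cross_validate, fold_table

spec = fl.SyntheticSpec()                      # 50x30, rank-2 planted structure
graph, _ = fl.planted_bipartite(spec)
seqs = {**fl.random_sequences(graph.pseudogene_ids, spec.pseudogene_length_range, seed=1),
        **fl.random_sequences(graph.mirna_ids, spec.mirna_length_range, seed=2)}
feats = fl.featurize_nodes(graph, seqs, k=3)
report = cross_validate(graph, feats, RunConfig.desk(seed=0))
print(fold_table(report).round(4).to_string(index=False))
```

prints (about 80 s on one CPU):

```
fold    auc   aupr  precision  recall     f1
   1 0.5900 0.5666     0.5952  0.5814 0.5882
   2 0.5733 0.5837     0.5556  0.5814 0.5682
   3 0.6690 0.6142     0.6226  0.7674 0.6875
   4 0.6587 0.6372     0.5957  0.6667 0.6292
   5 0.5567 0.5137     0.5303  0.8333 0.6481
mean 0.6096 0.5831     0.5799  0.6860 0.6243
```

The mean AUC of 0.61 is well above the permuted-label chance level of
0.5 (whose null standard deviation for these fold sizes is ≈ 0.028):
the model recovers the planted low-rank association structure from
topology alone. The ceiling here is ≈ 0.85 — the benchmark flips 5% of
cells, so a third of the observed edges are noise; simple 3-path
counting reaches only ≈ 0.59 on the same folds.

The same pipeline is exposed as a thin CLI for shell use
(`freqlink simulate | crossval | imbalance | predict`), and
`examples/` contains one short narrative script per capability
(featurization, spectral pooling, subgraph sampling, cross-validation).

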