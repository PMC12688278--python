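# Methods

## Problem and model

`freqlink` predicts unobserved links in a bipartite association graph
G = (V, ξ) between pseudogenes P = (p₁…p_N) and miRNAs M = (m₁…m_A).
Known associations are the edges ξ; candidate pairs are scored in (0, 1).
The model combines three ingredients:

1. **Spectral (optimal-frequency) node features.** Every node starts from
   its k-mer frequency profile (dimension 4^k, default k = 3 → 64). On the
   symmetric normalized Laplacian L = I − D^{−1/2} A D^{−1/2} (eigenvalues
   in [0, 2]), two pooling branches produce complementary views:
   - *Rayleigh pooling* (high frequency). Channel j's Rayleigh quotient
     r_j = x_jᵀLx_j / x_jᵀx_j measures how much of its energy lies at high
     graph frequencies. Channels are reweighted by
     w = n_ch · softmax(μ·r) — so μ = 0 gives every channel weight 1 — and
     the high-pass component L·X is added with gain ϑ before a learnable
     projection: H_RQ = σ((ϑ·LX + X)·diag(w)·W_rq). ϑ and μ are learnable
     scalars initialized at 1.
   - *Chebyshev pooling* (low frequency). A polynomial filter
     g(L) = Σ_{k≤K} θ_k T_k(L̃), L̃ = L − I, applied through the Chebyshev
     recurrence (no eigendecomposition; λ_max is fixed at 2, which bounds
     the spectrum of any symmetric normalized Laplacian). Coefficients are
     learnable, initialized to the exact degree-K expansion of the linear
     low-pass g(λ) = 1 − λ/2 (θ₀ = ½, θ₁ = −½, rest 0), so the branch
     starts smooth-passing; K defaults to 3.
   Both branches use a leaky rectifier (slope 0.01). The fusion
   Embeddings = π·H_RQ + (1−π)·H_CWT is convex; π defaults to a fixed 0.5
   and can optionally be made learnable (sigmoid of a logit, keeping it in
   [0, 1]). The "fused graph" is the original topology carrying the fused
   features — edges are never rewired, because downstream sampling needs
   the observed topology.

2. **Two structural views per candidate pair.**
   - *Local*: the enclosing subgraph. Starting from {p}, {m}, k rounds of
     simultaneous expansion add the miRNA neighbours of the current
     pseudogene set and the pseudogene neighbours of the current miRNA
     set, both computed from the round-start sets. Because both updates
     use the round-start sets, seeding from the miRNA or the pseudogene
     side yields the same sets; the local view is implemented as the
     union of both runs. The candidate edge is deleted from the induced
     subgraph — a positive pair never sees its own label. The nominal
     round budget ⌊v·e/2⌋ is astronomically large for any realistic graph
     (8,520 already at 80 nodes / 213 edges), so expansion stops as soon
     as the node set saturates, which happens at the connected component;
     the effective hop count is the config `k_hops` (default 3).
   - *Global*: random walk with restart from the pseudogene, the fixed
     point of ρ = c·A·D^{−1}·ρ + (1−c)·e, solved by power iteration from
     ρ₀ = e to an L1 tolerance of 1e-8 (the iteration is a contraction for
     c < 1; a 10,000-iteration guard exists but cannot trigger). In a
     bipartite graph every odd-hop node from a pseudogene is a miRNA, so
     the global view keeps the `top_n` miRNAs by ρ (default 20) plus any
     pseudogene adjacent to at least two retained nodes, so the length-2
     paths connecting the selected miRNAs survive induction. A pseudogene
     whose every edge is held out has no walk; the local view then stands
     alone.
   The two views are merged by node/edge union, with the candidate edge
   kept absent.

3. **Encoder, scorer and loss.** A two-layer GCN
   Z = Â·relu(Â·X·W₁)·W₂, Â = D̂^{−1/2}(A+I)D̂^{−1/2}, encodes the merged
   subgraph (dropout on the hidden layer in training mode only). Pair
   scores are sigmoid(MLP([z_p ‖ z_m])) with one hidden layer of the
   configured width. The training loss is

       (1 − α − β)·(L_cl + L_kl) + L_bce

   - L_cl: bilinear contrastive loss Γ(h_a, h_b) = sigmoid(h_aᵀ·W·h_b)
     between the two spectral branches; aligned rows are positives and a
     seeded cyclic row shift (a derangement) of H_CWT provides negatives.
     With an uninformative discriminator the loss equals ln 2.
   - L_kl: rows of the local- and global-view embeddings over their
     shared nodes are softmax-normalized and compared by KL divergence
     (in nats). This is the alignment term between the branch geometries;
     a literal log-ratio sum of raw embeddings is not a divergence.
   - L_bce: binary cross-entropy over the batch, probabilities clipped to
     [1e-7, 1 − 1e-7] (as are all log arguments).
   - α, β are learnable through a 3-way softmax over logits (the third
     slot anchors BCE), which keeps 1 − α − β inside [0, 1]; raw
     unconstrained weights could flip the sign of the auxiliary terms.

   Optimization is Adam (the reference protocol names only the learning
   rate, 1e-4); parameters of both pooling branches, the encoder, the
   scorer, the discriminator and the loss weights all receive gradients.
   Gradients come from a small reverse-mode automatic-differentiation
   engine over numpy arrays (`freqlink.autodiff`); its correctness is
   pinned by finite-difference checks in the test suite.

## Training and evaluation protocol

Negatives are drawn once per run, uniformly without replacement from the
non-edges, at `neg_ratio` negatives per positive (default 1). Folds are
stratified by label only: positives and negatives are shuffled and split
separately into k near-equal blocks, so every fold preserves the global
ratio within rounding. For each fold the graph used for training *and
sampling* has the fold's positive edges removed — no test association can
appear in any sampled structure. A label-stratified 10% validation split
is carved from the training pairs; early stopping restores the
best-validation-BCE snapshot after `patience` epochs without improvement.
One master seed fans out (via `numpy.random.SeedSequence`) to negative
sampling, folding, initialization, shuffling, dropout and the contrastive
shuffle, so a run is bit-reproducible.

Metrics: AUC (tie-corrected Mann–Whitney), AUPR (interpolation-free step
sum), precision/recall/F1 at threshold 0.5, plus confusion counts; all
via scikit-learn, cross-checked in the tests against a brute-force
concordance oracle. With a single class present the ranking metrics are
NaN with a warning. The imbalance sweep repeats cross-validation at
ratios 1:1, 1:2, 1:5, 1:10.

## Synthetic benchmark

The generator plants rank-r structure: latent factors u_i, v_j ~
N(0, 1/√r) per side, edge probabilities sigmoid(u_i·v_j) thresholded at
the quantile matching the target density, then every cell flipped
independently with probability `noise`. Defaults: 50 pseudogenes × 30
miRNAs, rank 2, density 0.10 (≈ 200 realized edges after the 5% noise
flips), noise 0.05. Sequences are uniform i.i.d. RNA (pseudogenes 100–300
nt, miRNAs 19–25 nt, the typical mature-miRNA range) and carry no planted
signal: features exercise the plumbing, topology carries the learnable
signal. What passing the end-to-end check shows is therefore that the
pipeline recovers *structural* association signal; it says nothing about
sequence-level biology, degree distributions of real interaction
databases, or ceRNA mechanisms, none of which the generator imitates.
The 5% flip noise is substantial at this scale — roughly a third of the
realized edges are spurious — so the latent-oracle ceiling on held-out
AUC is about 0.85 and plain path-count heuristics reach only ≈ 0.59.

## Sizing and numerical choices

- Desk-scale runs (`RunConfig.desk()`: examples, end-to-end tests, the
  acceptance script) use 30 epochs, patience 10, learning rate 1e-3,
  k_hops 2 and top_n 10 — a sizing chosen for the 50×30 benchmark, where
  the full-scale schedule (200 epochs at 1e-4) is needlessly long and
  the graph's diameter makes deep hops redundant. Full-scale defaults
  remain on `RunConfig` itself (lr 1e-4, batch 32, hidden 64, dropout
  0.3, k_hops 3, c 0.5, K 3, 5 folds).
- λ_max = 2 exactly; isolated nodes get identity Laplacian rows.
- Per-channel Rayleigh quotients of all-zero channels are defined as 0.
- RWR top-n ties break by node index (stable ranking).
- The per-batch KL term averages over the batch's pairs; pairs whose
  pseudogene is edge-free contribute no KL term.
- Fold sizes differ by at most 1 per class (array-split stratification).

## Known limitations

- The enclosing-subgraph features carry no distance labeling, so the
  encoder distinguishes candidate pairs only through the sampled
  topology and the spectral features; on very sparse graphs local views
  of different pairs can coincide.
- The exact algebraic form of the two pooling branches is a minimal
  construction honoring their stated roles (high-frequency gain ϑ,
  high-frequency channel weighting μ, learnable low-pass polynomial);
  other parameterizations with the same limiting behaviour exist.
- Training cost grows linearly in pairs × epochs with three subgraph
  encodings per pair per step; the implementation is dense-matrix numpy,
  adequate for graphs of a few hundred nodes per side.
- Scores are not calibrated probabilities; threshold metrics use 0.5.
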