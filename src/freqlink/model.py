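"""Encoder, discriminator, pair scorer and the composite training loss.

The encoder is a two-layer graph convolution on a sampled (merged)
subgraph, Z = A_hat relu(A_hat X W1) W2 with the renormalized adjacency
A_hat = D_hat^{-1/2} (A + I) D_hat^{-1/2}.  Pairs are scored by a one-
hidden-layer MLP on the concatenated endpoint embeddings.  Training
minimizes

    (1 - alpha - beta) * (L_cl + L_kl) + L_bce

where L_cl is a bilinear contrastive loss tying the high- and
low-frequency spectral branches together (aligned rows are positives,
row-shuffled rows negatives), L_kl aligns the local and global branch
embeddings through a row-softmax KL divergence, and L_bce is the usual
binary cross-entropy on the pair labels.  alpha and beta come from a
softmax over three logits, which keeps the contrastive weight
1 - alpha - beta inside [0, 1] by construction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, Adam, as_tensor, concat_cols, softmax_rows
from .sampling import SampledGraph

__all__ = ["EncoderParams", "gcn_normalize", "gcn_encode", "discriminator",
           "loss_cl", "loss_kl", "loss_bce", "loss_weights", "total_loss",
           "score_pairs"]

_EPS = 1e-7


class EncoderParams:
    """All learnable parameters of the encoder, scorer and discriminator."""

    def __init__(self, in_dim: int, hidden: int = 64, dropout_p: float = 0.3,
                 rng: np.random.Generator | None = None):
        if not (0.0 <= dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        rng = rng or np.random.default_rng(0)

        def glorot(shape):
            s = np.sqrt(2.0 / sum(shape))
            return Tensor(rng.normal(0.0, s, shape), requires_grad=True)

        self.W1 = glorot((in_dim, hidden))
        self.W2 = glorot((hidden, hidden))
        self.mlp_W = glorot((2 * hidden, hidden))
        self.mlp_b = Tensor(np.zeros(hidden), requires_grad=True)
        self.mlp_v = glorot((hidden, 1))
        self.mlp_c = Tensor(np.zeros(1), requires_grad=True)
        self.disc_W = glorot((in_dim, in_dim))
        self.mix_logits = Tensor(np.zeros(3), requires_grad=True)
        self.dropout_p = dropout_p
        self.hidden = hidden

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2, self.mlp_W, self.mlp_b, self.mlp_v,
                self.mlp_c, self.disc_W, self.mix_logits]


def gcn_normalize(A: np.ndarray) -> np.ndarray:
    """Renormalized adjacency D_hat^{-1/2} (A + I) D_hat^{-1/2}."""
    A_hat = np.asarray(A, dtype=np.float64) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return (dinv[:, None] * A_hat) * dinv[None, :]


def gcn_encode(sub: SampledGraph, X_full, params: EncoderParams,
               training: bool = False,
               rng: np.random.Generator | None = None):
    """Two-layer GCN on a sampled subgraph.

    `X_full` holds features for *all* parent nodes (array or Tensor); the
    subgraph's rows are gathered by global index.  Returns (Z, order)
    where `order` maps Z's rows back to global node indices.  Dropout is
    applied to the hidden layer only in training mode.
    """
    order = sub.node_order()
    X = as_tensor(X_full)
    if X.shape[0] != sub.parent.n_nodes:
        raise ValueError("feature rows must cover every parent node")
    A_hat = Tensor(gcn_normalize(sub.adjacency()))
    Xs = X.take_rows(order)
    H = (A_hat @ Xs @ params.W1).relu()
    if training and params.dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(H.shape) >= params.dropout_p) / (1.0 - params.dropout_p)
        H = H * Tensor(keep)
    Z = A_hat @ H @ params.W2
    return Z, order


def discriminator(h_a, h_b, disc_W) -> Tensor:
    """Bilinear similarity sigmoid(h_a^T W h_b).

    1-D inputs give a scalar; 2-D inputs are scored row-against-row.
    """
    h_a, h_b, W = as_tensor(h_a), as_tensor(h_b), as_tensor(disc_W)
    if h_a.ndim == 1:
        return (h_a @ W @ h_b).sigmoid()
    return ((h_a @ W) * h_b).sum(axis=1).sigmoid()


def loss_cl(H_RQ, H_CWT, disc_W, seed: int = 0) -> Tensor:
    """Contrastive loss between the two spectral branches.

    Positives pair each node's high-frequency row with its own
    low-frequency row; negatives use a cyclic row shift (a seeded
    derangement) of the low-frequency rows.  Mean of 2|V| log terms.
    """
    H_RQ, H_CWT = as_tensor(H_RQ), as_tensor(H_CWT)
    n = H_RQ.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 nodes")
    shift = int(np.random.default_rng(seed).integers(1, n))
    perm = np.roll(np.arange(n), shift)
    pos = discriminator(H_RQ, H_CWT, disc_W).clip(_EPS, 1.0 - _EPS)
    neg = discriminator(H_RQ, H_CWT.take_rows(perm), disc_W).clip(_EPS, 1.0 - _EPS)
    return -0.5 * (pos.log().mean() + (1.0 - neg).log().mean())


def loss_kl(Z_m, Z_rwr) -> Tensor:
    """Row-softmax KL divergence KL(q || r) between the local-branch and
    global-branch embeddings over their shared node set, averaged over rows."""
    Z_m, Z_rwr = as_tensor(Z_m), as_tensor(Z_rwr)
    if Z_m.shape != Z_rwr.shape:
        raise ValueError("embedding shapes differ")
    if Z_m.shape[0] == 0:
        raise ValueError("empty shared node set")
    q = softmax_rows(Z_m).clip(_EPS, 1.0)
    r = softmax_rows(Z_rwr).clip(_EPS, 1.0)
    return (q * (q.log() - r.log())).sum(axis=1).mean()


def loss_bce(y, y_hat) -> Tensor:
    """Binary cross-entropy with probability clipping."""
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty batch")
    p = as_tensor(y_hat).clip(_EPS, 1.0 - _EPS)
    yt = Tensor(y)
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()


def loss_weights(mix_logits) -> tuple[Tensor, Tensor]:
    """(alpha, beta) from a 3-way softmax, so 1 - alpha - beta stays in [0, 1]."""
    s = softmax_rows(as_tensor(mix_logits))
    return s.take_rows([0]).sum(), s.take_rows([1]).sum()


def total_loss(l_cl, l_kl, l_bce, alpha, beta) -> Tensor:
    """(1 - alpha - beta) * (L_cl + L_kl) + L_bce."""
    alpha, beta = as_tensor(alpha), as_tensor(beta)
    w = 1.0 - alpha - beta
    if not -1e-9 <= float(w.data) <= 1.0 + 1e-9:
        raise ValueError("1 - alpha - beta must lie in [0, 1]")
    return w * (as_tensor(l_cl) + as_tensor(l_kl)) + as_tensor(l_bce)


def score_pairs(Z, order: np.ndarray, pairs_global, params: EncoderParams) -> Tensor:
    """MLP pair scores sigmoid(v^T relu(W [z_p || z_m] + b) + c).

    `pairs_global` is an iterable of (pseudogene_global, mirna_global)
    node indices, all of which must be present in `order` (the global
    indices of Z's rows).
    """
    pos = {g: i for i, g in enumerate(order)}
    try:
        rows_p = [pos[p] for p, _ in pairs_global]
        rows_m = [pos[m] for _, m in pairs_global]
    except KeyError as exc:
        raise KeyError(f"pair endpoint {exc} not in sampled graph") from exc
    Z = as_tensor(Z)
    zp = Z.take_rows(rows_p)
    zm = Z.take_rows(rows_m)
    h = (concat_cols(zp, zm) @ params.mlp_W + params.mlp_b).relu()
    return (h @ params.mlp_v + params.mlp_c).sigmoid().reshape(-1)
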