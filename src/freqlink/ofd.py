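"""Optimal-frequency discovery: spectral pooling of node features.

Two branches extract complementary spectral views of the node features on
the association graph's symmetric normalized Laplacian L = I - D^{-1/2} A
D^{-1/2} (eigenvalues in [0, 2]):

* **Rayleigh pooling** (high frequency): each feature channel's Rayleigh
  quotient r_j = x_j^T L x_j / x_j^T x_j measures how much of its energy
  sits at high graph frequencies.  Channels are reweighted by a softmax in
  mu * r (temperature mu, scaled so the uniform case gives weight 1 per
  channel) and the signal is sharpened by adding theta * L X — the
  high-pass component — before projection, so rough, locally fluctuating
  channels are amplified.
* **Chebyshev pooling** (low frequency): a learnable polynomial filter
  g(L) = sum_k theta_k T_k(Lt), Lt = L - I, applied via the Chebyshev
  recurrence (no eigendecomposition).  Coefficients are initialized to the
  degree-K Chebyshev expansion of the linear low-pass g(lambda) =
  1 - lambda/2, so the branch starts smooth-passing.

The two branch outputs are fused convexly, ``pi * h_rq + (1-pi) * h_cwt``,
and installed as node features on the original topology (the "fused
graph"); edges are never rewired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, softmax_rows

__all__ = ["SpectralOperator", "normalized_laplacian", "laplacian_from_adjacency",
           "rayleigh_quotient", "rayleigh_pool", "chebyshev_pool", "fuse",
           "cheb_lowpass_init", "cheb_filter_response", "FusedGraph", "OFD"]


@dataclass
class SpectralOperator:
    """Symmetric normalized Laplacian and its [-1, 1]-rescaled form."""

    laplacian: np.ndarray
    lambda_max: float = 2.0

    @property
    def scaled_laplacian(self) -> np.ndarray:
        n = self.laplacian.shape[0]
        return (2.0 / self.lambda_max) * self.laplacian - np.eye(n)

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]


def laplacian_from_adjacency(A: np.ndarray) -> SpectralOperator:
    """L = I - D^{-1/2} A D^{-1/2}; isolated nodes get an identity row."""
    A = np.asarray(A, dtype=np.float64)
    d = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    L = np.eye(A.shape[0]) - (dinv[:, None] * A) * dinv[None, :]
    return SpectralOperator(L)


def normalized_laplacian(graph) -> SpectralOperator:
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    return laplacian_from_adjacency(graph.adjacency)


def rayleigh_quotient(op: SpectralOperator, x: np.ndarray) -> float:
    """(x^T L x) / (x^T x): Laplacian-weighted signal energy, in [0, 2]."""
    x = np.asarray(x, dtype=np.float64)
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("Rayleigh quotient undefined for the zero vector")
    return float(x @ op.laplacian @ x) / denom


def _channel_rayleigh(op: SpectralOperator, X: np.ndarray) -> np.ndarray:
    """Per-channel Rayleigh quotients; all-zero channels count as 0."""
    norms = (X * X).sum(axis=0)
    energy = (X * (op.laplacian @ X)).sum(axis=0)
    return np.where(norms > 0, energy / np.where(norms > 0, norms, 1.0), 0.0)


def _apply_activation(t: Tensor, activation: str) -> Tensor:
    if activation == "leaky_relu":
        return t.leaky_relu(0.01)
    if activation == "linear":
        return t
    if activation == "relu":
        return t.relu()
    raise ValueError(f"unknown activation {activation!r}")


def rayleigh_pool(op: SpectralOperator, X: np.ndarray, theta_rq, mu_rq, W,
                  activation: str = "leaky_relu") -> Tensor:
    """High-frequency branch.

    h = act( (theta * L X + X) diag(w) W ) with channel weights
    w = n_channels * softmax(mu * r), r the per-channel Rayleigh quotients.
    theta (high-pass gain), mu (temperature) and W may be learnable tensors.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != op.n_nodes:
        raise ValueError(f"feature rows ({X.shape[0]}) != nodes ({op.n_nodes})")
    theta, mu, W = as_tensor(theta_rq), as_tensor(mu_rq), as_tensor(W)
    r = Tensor(_channel_rayleigh(op, X))
    w = softmax_rows(mu * r) * float(X.shape[1])
    x_hp = Tensor(op.laplacian @ X)
    pooled = (theta * x_hp + Tensor(X)) * w  # broadcast weights over rows
    return _apply_activation(pooled @ W, activation)


def chebyshev_pool(op: SpectralOperator, X: np.ndarray, cheb_coeffs, W,
                   activation: str = "leaky_relu") -> Tensor:
    """Low-frequency branch: h = act( (sum_k theta_k T_k(Lt) X) W )."""
    X = np.asarray(X, dtype=np.float64)
    coeffs = as_tensor(cheb_coeffs)
    K = coeffs.data.shape[0] - 1
    if K < 0:
        raise ValueError("need at least one Chebyshev coefficient (K >= 0)")
    if X.shape[0] != op.n_nodes:
        raise ValueError("feature rows != node count")
    Lt = op.scaled_laplacian
    terms = [X]
    if K >= 1:
        terms.append(Lt @ X)
    for _ in range(2, K + 1):
        terms.append(2.0 * (Lt @ terms[-1]) - terms[-2])
    acc = coeffs.take_rows([0]) * Tensor(terms[0])
    for k in range(1, K + 1):
        acc = acc + coeffs.take_rows([k]) * Tensor(terms[k])
    return _apply_activation(acc @ as_tensor(W), activation)


def cheb_lowpass_init(K: int) -> np.ndarray:
    """Chebyshev coefficients of the linear low-pass g(lambda) = 1 - lambda/2.

    On the rescaled variable lt = lambda - 1 this is (1 - lt)/2, whose
    exact expansion is theta_0 = 1/2, theta_1 = -1/2, higher orders 0.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    coeffs = np.zeros(K + 1)
    coeffs[0] = 0.5
    if K >= 1:
        coeffs[1] = -0.5
    return coeffs


def cheb_filter_response(coeffs: np.ndarray, lambdas: np.ndarray,
                         lambda_max: float = 2.0) -> np.ndarray:
    """Filter gain g(lambda) = sum_k theta_k T_k(2 lambda/lambda_max - 1)."""
    lt = np.asarray(lambdas, dtype=np.float64) * (2.0 / lambda_max) - 1.0
    out = np.zeros_like(lt)
    t_prev, t_cur = np.ones_like(lt), lt.copy()
    for k, th in enumerate(np.asarray(coeffs, dtype=np.float64)):
        if k == 0:
            out += th * t_prev
        elif k == 1:
            out += th * t_cur
        else:
            t_prev, t_cur = t_cur, 2.0 * lt * t_cur - t_prev
            out += th * t_cur
    return out


@dataclass
class FusedGraph:
    """Original topology with the fused spectral embedding as node features."""

    graph: object           # the BipartiteGraph the features live on
    features: Tensor        # n_nodes x d fused node features
    h_rq: Tensor = None
    h_cwt: Tensor = None


def fuse(h_rq, h_cwt, pi: float):
    """Convex fusion pi * h_rq + (1 - pi) * h_cwt of the two branches."""
    pi_val = float(pi.data) if isinstance(pi, Tensor) else float(pi)
    if not (0.0 <= pi_val <= 1.0):
        raise ValueError("pi must lie in [0, 1]")
    h_rq, h_cwt = as_tensor(h_rq), as_tensor(h_cwt)
    if h_rq.shape != h_cwt.shape:
        raise ValueError("branch shapes differ")
    return as_tensor(pi) * h_rq + (1.0 - as_tensor(pi)) * h_cwt


class OFD:
    """Learnable optimal-frequency discovery module.

    Bundles the parameters of both pooling branches and produces the fused
    node features for a graph.  `pi` is a fixed scalar by default; with
    ``learnable_pi`` it becomes sigmoid of a trainable logit so it stays
    in [0, 1].
    """

    def __init__(self, in_dim: int, out_dim: int, cheb_order: int = 3,
                 pi: float = 0.5, learnable_pi: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.theta_rq = Tensor(1.0, requires_grad=True)
        self.mu_rq = Tensor(1.0, requires_grad=True)
        self.W_rq = Tensor(rng.normal(0, scale, (in_dim, out_dim)), requires_grad=True)
        self.cheb_coeffs = Tensor(cheb_lowpass_init(cheb_order), requires_grad=True)
        self.W_cwt = Tensor(rng.normal(0, scale, (in_dim, out_dim)), requires_grad=True)
        self.learnable_pi = learnable_pi
        if learnable_pi:
            logit = float(np.log(pi / (1.0 - pi))) if 0 < pi < 1 else 0.0
            self.pi_logit = Tensor(logit, requires_grad=True)
        else:
            if not (0.0 <= pi <= 1.0):
                raise ValueError("pi must lie in [0, 1]")
            self.pi = pi

    def parameters(self) -> list[Tensor]:
        ps = [self.theta_rq, self.mu_rq, self.W_rq, self.cheb_coeffs, self.W_cwt]
        if self.learnable_pi:
            ps.append(self.pi_logit)
        return ps

    def forward(self, op: SpectralOperator, X: np.ndarray, graph=None) -> FusedGraph:
        h_rq = rayleigh_pool(op, X, self.theta_rq, self.mu_rq, self.W_rq)
        h_cwt = chebyshev_pool(op, X, self.cheb_coeffs, self.W_cwt)
        pi = self.pi_logit.sigmoid() if self.learnable_pi else self.pi
        fused = fuse(h_rq, h_cwt, pi)
        return FusedGraph(graph=graph, features=fused, h_rq=h_rq, h_cwt=h_cwt)
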