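"""Training loop, cross-validation driver and ranking metrics.

One training step works on a batch of candidate pairs: the spectral
module recomputes the fused node features, each pair's merged
local/global subgraph is encoded by the two-layer GCN and scored by the
MLP head, and the composite loss (contrastive + KL + BCE, see
:mod:`freqlink.model`) is minimized with Adam.  Early stopping watches
the BCE on a validation split carved from the training pairs.

Cross-validation removes every test-fold positive edge from the graph a
fold trains and samples on, so no test association can leak into the
structures the model learns from.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             roc_auc_score)

from . import model as M
from .autodiff import Adam, Tensor, stack1d
from .graph_io import BipartiteGraph, LabeledPairs, make_folds, sample_negatives
from .model import EncoderParams
from .ofd import OFD, normalized_laplacian
from .sampling import local_subgraph, merge_graphs, rwr_graph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "MetricsReport", "TrainedModel", "train",
           "compute_metrics", "cross_validate", "imbalance_sweep", "fold_table"]


@dataclass
class RunConfig:
    """Hyperparameters; defaults follow the reference protocol."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    hidden: int = 64
    dropout: float = 0.3
    k_hops: int = 3
    restart_c: float = 0.5
    pi: float = 0.5
    learnable_pi: bool = False
    cheb_order: int = 3
    top_n: int = 20
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    neg_ratio: float = 1.0
    k_folds: int = 5
    kmer_k: int = 3

    def __post_init__(self):
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("learning_rate", "batch_size", "hidden", "epochs",
                     "k_folds", "neg_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Down-scaled settings for the small planted synthetic graphs
        (fewer epochs, shallower hops, a faster learning rate)."""
        base = dict(learning_rate=1e-3, epochs=30, patience=10,
                    k_hops=2, top_n=10)
        base.update(overrides)
        return cls(**base)


@dataclass
class MetricsReport:
    """Per-fold metric rows plus their mean and standard deviation."""

    folds: list[dict] = field(default_factory=list)

    _KEYS = ("auc", "aupr", "precision", "recall", "f1")

    @property
    def mean(self) -> dict:
        return {k: float(np.mean([f[k] for f in self.folds])) for k in self._KEYS}

    @property
    def sd(self) -> dict:
        return {k: float(np.std([f[k] for f in self.folds], ddof=1))
                if len(self.folds) > 1 else 0.0 for k in self._KEYS}

    @property
    def confusion(self) -> dict:
        keys = ("tn", "fp", "fn", "tp")
        return {k: int(sum(f[k] for f in self.folds)) for k in keys}


def compute_metrics(y, y_hat, threshold: float = 0.5) -> dict:
    """AUC, AUPR and threshold metrics for one set of scored pairs.

    AUC is the tie-corrected Mann-Whitney statistic; AUPR the
    interpolation-free step sum of the precision-recall curve.  With a
    single class present the ranking metrics are undefined (NaN, with a
    warning); threshold metrics are still returned.
    """
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label/score length mismatch")
    pred = (y_hat >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUC/AUPR undefined", stacklevel=2)
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(y, y_hat))
        aupr = float(average_precision_score(y, y_hat))
    return {"auc": auc, "aupr": aupr, "precision": float(prec),
            "recall": float(rec), "f1": float(f1),
            "tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)}


class TrainedModel:
    """A fitted model bound to the graph it was trained (and samples) on."""

    def __init__(self, graph: BipartiteGraph, X: np.ndarray, config: RunConfig,
                 seed: int):
        self.graph = graph
        self.X = np.asarray(X, dtype=np.float64)
        self.config = config
        self.op = normalized_laplacian(graph)
        rng = np.random.default_rng(seed)
        self.ofd = OFD(self.X.shape[1], config.hidden, cheb_order=config.cheb_order,
                       pi=config.pi, learnable_pi=config.learnable_pi, rng=rng)
        self.enc = EncoderParams(config.hidden, hidden=config.hidden,
                                 dropout_p=config.dropout, rng=rng)
        self._samples: dict[tuple[int, int], tuple] = {}

    # -- sampling cache ------------------------------------------------------
    def _sample(self, pair: tuple[int, int]):
        """(merged, local, global) sampled graphs for a side-local pair.

        A pseudogene left with no edges (all its associations held out)
        has no defined RWR profile; the local view then stands alone.
        """
        key = (int(pair[0]), int(pair[1]))
        hit = self._samples.get(key)
        if hit is not None:
            return hit
        cfg = self.config
        loc = local_subgraph(self.graph, key, cfg.k_hops)
        try:
            glo = rwr_graph(self.graph, key[0], c=cfg.restart_c, top_n=cfg.top_n)
            merged = merge_graphs(loc, glo)
        except ValueError:
            glo = None
            merged = merge_graphs(loc, loc)
        self._samples[key] = (merged, loc, glo)
        return self._samples[key]

    def parameters(self) -> list[Tensor]:
        return self.ofd.parameters() + self.enc.parameters()

    # -- forward passes ------------------------------------------------------
    def _batch_forward(self, pairs: np.ndarray, training: bool,
                       rng: np.random.Generator | None = None,
                       with_kl: bool = False):
        """Scores (and optional mean KL term) for an array of pairs."""
        fused = self.ofd.forward(self.op, self.X, self.graph)
        scores, kl_terms = [], []
        for pair in pairs:
            merged, loc, glo = self._sample(tuple(pair))
            Z, order = M.gcn_encode(merged, fused.features, self.enc,
                                    training=training, rng=rng)
            gp, gm = self.graph.pair_to_global(tuple(pair))
            scores.append(M.score_pairs(Z, order, [(gp, gm)], self.enc))
            if with_kl and glo is not None:
                Zl, ol = M.gcn_encode(loc, fused.features, self.enc,
                                      training=training, rng=rng)
                Zg, og = M.gcn_encode(glo, fused.features, self.enc,
                                      training=training, rng=rng)
                shared = sorted(set(ol) & set(og))
                if shared:
                    pl = {g: i for i, g in enumerate(ol)}
                    pg = {g: i for i, g in enumerate(og)}
                    kl_terms.append(M.loss_kl(
                        Zl.take_rows([pl[g] for g in shared]),
                        Zg.take_rows([pg[g] for g in shared])))
        y_hat = stack1d(scores)
        kl = None
        if with_kl:
            if kl_terms:
                kl = kl_terms[0]
                for t in kl_terms[1:]:
                    kl = kl + t
                kl = kl / float(len(kl_terms))
            else:
                kl = Tensor(0.0)
        return y_hat, fused, kl

    def predict(self, pairs) -> np.ndarray:
        """Association scores in (0, 1) for (pseudogene, miRNA) index pairs."""
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        y_hat, _, _ = self._batch_forward(pairs, training=False)
        return y_hat.data.copy()

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()


def _split_validation(pairs: LabeledPairs, fraction: float,
                      rng: np.random.Generator) -> tuple[LabeledPairs, LabeledPairs]:
    """Label-stratified train/validation split."""
    val_mask = np.zeros(len(pairs), dtype=bool)
    for label in (0, 1):
        idx = np.flatnonzero(pairs.labels == label)
        rng.shuffle(idx)
        n_val = int(round(fraction * idx.size))
        val_mask[idx[:n_val]] = True
    if val_mask.all() or not val_mask.any():
        return pairs, pairs.subset(np.zeros(len(pairs), dtype=bool))
    return pairs.subset(~val_mask), pairs.subset(val_mask)


def train(graph: BipartiteGraph, features, config: RunConfig,
          pairs: LabeledPairs | None = None, seed: int | None = None,
          log_path=None) -> TrainedModel:
    """Fit the model on labeled pairs over a graph.

    `features` is the (pseudogene, miRNA) FeatureMatrix tuple; when
    `pairs` is omitted, negatives are sampled at the configured ratio.
    Deterministic for a given seed (default: config.seed).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_init, s_split, s_shuffle, s_drop, s_cl = ss.spawn(5)
    if pairs is None:
        pairs = sample_negatives(graph, config.neg_ratio,
                                 seed=int(s_split.generate_state(1)[0] % 2**31))
    if int(pairs.labels.sum()) == 0:
        raise ValueError("no positive training pairs")
    P_feat, M_feat = features
    X = np.vstack([P_feat.values, M_feat.values])
    model = TrainedModel(graph, X, config,
                         seed=int(s_init.generate_state(1)[0] % 2**31))
    train_p, val_p = _split_validation(
        pairs, config.val_fraction, np.random.default_rng(s_split))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(s_shuffle)
    drop_rng = np.random.default_rng(s_drop)
    cl_rng = np.random.default_rng(s_cl)

    best_val, best_snap, stale = np.inf, None, 0
    rows = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_p))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = train_p.pairs[order[start:start + config.batch_size]]
            y = train_p.labels[order[start:start + config.batch_size]]
            opt.zero_grad()
            y_hat, fused, l_kl = model._batch_forward(
                batch, training=True, rng=drop_rng, with_kl=True)
            l_bce = M.loss_bce(y, y_hat)
            l_cl = M.loss_cl(fused.h_rq, fused.h_cwt, model.enc.disc_W,
                             seed=int(cl_rng.integers(2**31)))
            alpha, beta = M.loss_weights(model.enc.mix_logits)
            loss = M.total_loss(l_cl, l_kl, l_bce, alpha, beta)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss = epoch_loss / max(n_batches, 1)
        if len(val_p):
            val_scores, _, _ = model._batch_forward(val_p.pairs, training=False)
            val_loss = float(M.loss_bce(val_p.labels, val_scores).data)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                     "val_loss": val_loss})
        logger.debug("epoch %d train %.4f val %.4f", epoch,
                     rows[-1]["train_loss"], val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_snap, stale = val_loss, model.snapshot(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_snap is not None:
        model.restore(best_snap)
    if log_path is not None:
        pd.DataFrame(rows).to_csv(log_path, sep="\t", index=False)
    return model


def cross_validate(graph: BipartiteGraph, features, config: RunConfig,
                   pairs: LabeledPairs | None = None) -> MetricsReport:
    """Stratified k-fold CV: per fold, retrain on a graph stripped of the
    fold's positive edges and score the held-out pairs."""
    if config.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    ss = np.random.SeedSequence(config.seed)
    s_neg, s_fold, *fold_seeds = ss.spawn(2 + config.k_folds)
    if pairs is None:
        pairs = sample_negatives(graph, config.neg_ratio,
                                 seed=int(s_neg.generate_state(1)[0] % 2**31))
    pairs = make_folds(pairs, config.k_folds,
                       seed=int(s_fold.generate_state(1)[0] % 2**31))
    report = MetricsReport()
    for f in range(config.k_folds):
        test = pairs.subset(pairs.fold == f)
        train_p = pairs.subset(pairs.fold != f)
        test_pos = {tuple(map(int, pr))
                    for pr, y in zip(test.pairs, test.labels) if y == 1}
        g_train = graph.without_edges(test_pos)
        mdl = train(g_train, features, config, pairs=train_p,
                    seed=int(fold_seeds[f].generate_state(1)[0] % 2**31))
        scores = mdl.predict(test.pairs)
        report.folds.append(compute_metrics(test.labels, scores))
        logger.info("fold %d: auc=%.4f aupr=%.4f", f,
                    report.folds[-1]["auc"], report.folds[-1]["aupr"])
    return report


def imbalance_sweep(graph: BipartiteGraph, features, config: RunConfig,
                    ratios=(1, 2, 5, 10)) -> dict[float, MetricsReport]:
    """Cross-validate at several positive:negative ratios (1:r)."""
    return {r: cross_validate(graph, features, replace(config, neg_ratio=float(r)))
            for r in ratios}


def fold_table(report: MetricsReport) -> pd.DataFrame:
    """Per-fold metric rows plus a final mean row."""
    rows = [{"fold": i + 1, **{k: f[k] for k in MetricsReport._KEYS}}
            for i, f in enumerate(report.folds)]
    rows.append({"fold": "mean", **report.mean})
    return pd.DataFrame(rows)


def sweep_table(reports: dict[float, MetricsReport]) -> pd.DataFrame:
    """Metrics (rows) by positive:negative ratio (columns)."""
    out = {f"1:{int(r)}": rep.mean for r, rep in reports.items()}
    return pd.DataFrame(out).loc[list(MetricsReport._KEYS)]
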