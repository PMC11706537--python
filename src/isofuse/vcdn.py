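"""Cross-omics integration in the label space.

The per-view GCN predictions for one isoform are combined into a
cross-omics discovery tensor — the T x T x T outer product of the three
predicted label distributions, flattened row-major — and a fully
connected network on that tensor produces the final per-term scores.
Joint training alternates: each view's GCN is updated on its own
gene-pooled weighted BCE, then, with the GCNs fixed, the integration
network is updated on the same objective applied to its own output.
Tensors are built per isoform minibatch, so peak memory grows as
O(batch x T^3) rather than O(n x T^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Parameter, Tensor
from .gcn import (
    GCNConfig,
    build_adjacency,
    compute_class_weights,
    gene_pool,
    train_gcn,
    wbce_loss,
)

logger = logging.getLogger("isofuse")

__all__ = [
    "VCDNConfig",
    "VCDN",
    "TrainSchedule",
    "build_tensor",
    "vcdn_forward",
    "joint_train",
]


def _glorot(rng, d_in, d_out):
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


@dataclass
class VCDNConfig:
    hidden: int = 0  # 0 -> ceil(T^3 / 2)
    lr: float = 1e-3
    lrelu_slope: float = 0.2
    seed: int = 0


@dataclass
class TrainSchedule:
    pretrain_epochs: int = 300
    joint_epochs: int = 250
    gcn_steps_per_epoch: int = 1
    vcdn_steps_per_epoch: int = 1
    patience: int = 50

    def __post_init__(self):
        for f in ("pretrain_epochs", "joint_epochs", "gcn_steps_per_epoch",
                  "vcdn_steps_per_epoch", "patience"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


def build_tensor(yhat1, yhat2, yhat3):
    """Flattened outer product of three per-view label distributions.

    Accepts T-vectors or n x T batches (tape Tensors or arrays); returns
    the T^3 (or n x T^3) cross-omics discovery vector with entry
    ``c[(e1*T + e2)*T + e3] = y1[e1] * y2[e2] * y3[e3]``.
    """
    tape = any(isinstance(y, Tensor) for y in (yhat1, yhat2, yhat3))
    ys = [y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
          for y in (yhat1, yhat2, yhat3)]
    single = ys[0].data.ndim == 1
    if single:
        ys = [y.reshape(1, -1) for y in ys]
    T = ys[0].shape[1]
    if any(y.shape[1] != T for y in ys):
        raise ValueError("per-view prediction lengths differ")
    n = ys[0].shape[0]
    c12 = ys[0].reshape(n, T, 1) * ys[1].reshape(n, 1, T)  # n x T x T
    c = c12.reshape(n, T * T, 1) * ys[2].reshape(n, 1, T)  # n x T^2 x T
    c = c.reshape(n, T * T * T)
    if single:
        c = c.reshape(T * T * T)
    return c if tape else np.asarray(c.data)


class VCDN:
    """One hidden layer on the flattened discovery tensor, sigmoid output."""

    def __init__(self, n_terms: int, cfg: VCDNConfig = None):
        cfg = cfg or VCDNConfig()
        self.cfg = cfg
        d_in = n_terms**3
        hidden = cfg.hidden or int(np.ceil(d_in / 2))
        rng = np.random.default_rng(cfg.seed)
        self.W1 = Parameter(_glorot(rng, d_in, hidden))
        self.b1 = Parameter(np.zeros(hidden))
        self.W2 = Parameter(_glorot(rng, hidden, n_terms))
        self.b2 = Parameter(np.zeros(n_terms))

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, c) -> Tensor:
        h = Tensor._lift(c)
        single = h.data.ndim == 1
        if single:
            h = h.reshape(1, -1)
        h = (h @ self.W1 + self.b1).leaky_relu(self.cfg.lrelu_slope)
        out = (h @ self.W2 + self.b2).sigmoid()
        return out.reshape(-1) if single else out


def vcdn_forward(c, model: VCDN):
    """Evaluate the integration network on one flattened tensor (or batch)."""
    out = model.forward(c)
    return out if isinstance(c, Tensor) else np.asarray(out.data)


def _vcdn_batch_predict(model: VCDN, preds, batch: int = 64) -> np.ndarray:
    """Stream tensor construction per minibatch to bound peak memory."""
    n = preds[0].shape[0]
    out = np.zeros((n, preds[0].shape[1]))
    for lo in range(0, n, batch):
        sl = slice(lo, min(lo + batch, n))
        c = build_tensor(preds[0][sl], preds[1][sl], preds[2][sl])
        out[sl] = np.asarray(model.forward(Tensor(c)).data)
    return out


def joint_train(bundle, iii, ann, split, gcn_cfgs=None, vcdn_cfg=None,
                schedule=None, iii_as_graph: bool = True):
    """Pretrain the three omics GCNs, then alternate GCN and VCDN updates.

    Views are (expression, sequence, III): the symmetrized III matrix
    serves as both the third feature matrix and (after the same
    edges-per-node thresholding) its own graph. Early stopping watches
    the integration loss on validation genes. Returns
    ``(gcns, vcdn, final_scores, info)`` with per-view initial predictions
    and loss traces inside ``info``.
    """
    schedule = schedule or TrainSchedule()
    vcdn_cfg = vcdn_cfg or VCDNConfig()
    if iii is None:  # interaction-generation ablation: raw PPI rows instead
        W = np.asarray(bundle.X3, dtype=np.float64)
    else:
        W = iii.W if hasattr(iii, "W") else np.asarray(iii)
    n_terms = ann.n_terms
    seg = bundle.gene_index_of_isoform
    g = bundle.n_genes
    Y = ann.Y

    views = [np.asarray(bundle.X1, dtype=np.float64),
             np.asarray(bundle.X2, dtype=np.float64),
             np.asarray(W, dtype=np.float64)]
    if gcn_cfgs is None:
        gcn_cfgs = [GCNConfig(seed=s) for s in (11, 12, 13)]
    for cfg in gcn_cfgs:
        cfg.epochs = cfg.epochs or schedule.pretrain_epochs

    graphs = [build_adjacency(v, cfg.a_edges) for v, cfg in zip(views, gcn_cfgs)]
    if not iii_as_graph:
        # alternative reading: the III matrix is itself the third graph,
        # normalized directly instead of re-thresholded by similarity
        from .gcn import GraphSpec, normalize_adjacency

        graphs[2] = GraphSpec(A=views[2], theta=0.0, a=gcn_cfgs[2].a_edges,
                              A_norm=normalize_adjacency(views[2]))

    # ---- stage 1: pretraining ------------------------------------------
    gcns, preds = [], []
    for v, gs, cfg in zip(views, graphs, gcn_cfgs):
        model, yhat = train_gcn(v, gs.A_norm, Y, seg, split, cfg)
        gcns.append(model)
        preds.append(yhat)
    pre_preds = [p.copy() for p in preds]

    # ---- stage 2: alternating joint training ---------------------------
    weights = compute_class_weights(Y[split.train_genes])
    vcdn = VCDN(n_terms, vcdn_cfg)
    opt_v = Adam(vcdn.params, lr=vcdn_cfg.lr)
    opts_g = [Adam(m.params, lr=c.lr) for m, c in zip(gcns, gcn_cfgs)]
    Xts = [Tensor(v) for v in views]
    Ats = [Tensor(gs.A_norm) for gs in graphs]

    def gcn_loss(k, training):
        yhat = gcns[k].forward(Xts[k], Ats[k], training=training)
        pooled = gene_pool(yhat, seg, g)
        return wbce_loss(pooled.take_rows(split.train_genes),
                         Y[split.train_genes], weights), yhat

    def vcdn_loss_on(genes):
        c = build_tensor(*[Tensor(p) for p in preds])
        out = vcdn.forward(c)
        pooled = gene_pool(out, seg, g)
        return wbce_loss(pooled.take_rows(genes), Y[genes], weights)

    best_val, best_state, bad = np.inf, None, 0
    trace = []
    for epoch in range(schedule.joint_epochs):
        for k in range(3):  # VCDN fixed, update each omics GCN
            for _ in range(schedule.gcn_steps_per_epoch):
                opts_g[k].zero_grad()
                loss, _ = gcn_loss(k, training=True)
                loss.backward()
                opts_g[k].step()
            yhat = gcns[k].forward(Xts[k], Ats[k], training=False)
            preds[k] = np.asarray(yhat.data)
        for _ in range(schedule.vcdn_steps_per_epoch):  # GCNs fixed, update VCDN
            opt_v.zero_grad()
            loss = vcdn_loss_on(split.train_genes)
            loss.backward()
            opt_v.step()
        if not np.isfinite(float(loss.data)):
            raise FloatingPointError(f"integration loss diverged at joint epoch {epoch}")
        monitor_genes = split.val_genes if len(split.val_genes) else split.train_genes
        vloss = float(vcdn_loss_on(monitor_genes).data)
        trace.append({"epoch": epoch, "vcdn_loss": float(loss.data), "val_loss": vloss})
        logger.info("joint epoch %d vcdn %.4f val %.4f", epoch, float(loss.data), vloss)
        if vloss < best_val - 1e-9:
            best_val, bad = vloss, 0
            best_state = (
                [[p.data.copy() for p in m.params] for m in gcns],
                [p.data.copy() for p in vcdn.params],
            )
        else:
            bad += 1
            if bad >= schedule.patience:
                logger.info("joint training early stop at epoch %d", epoch)
                break
    if best_state is not None:
        for m, state in zip(gcns, best_state[0]):
            for p, s in zip(m.params, state):
                p.data = s
        for p, s in zip(vcdn.params, best_state[1]):
            p.data = s
        for k in range(3):
            preds[k] = np.asarray(gcns[k].forward(Xts[k], Ats[k], training=False).data)

    final = _vcdn_batch_predict(vcdn, preds)
    info = {"initial_predictions": pre_preds, "joint_predictions": preds,
            "trace": trace, "graphs": graphs}
    return gcns, vcdn, final, info
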