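"""Omics-specific graph-convolutional classifiers.

For each omics view a cosine-similarity graph over isoforms is built and
thresholded so each node keeps a target mean number of edges; the
normalized operator P̄^{-1/2}(A+I)P̄^{-1/2} then drives a three-layer
graph convolution with a fully connected sigmoid head predicting GO-term
memberships per isoform. Training pools isoform scores to genes by max
(a gene's annotation is explained by its best-scoring isoform) and
minimizes a class-weighted binary cross-entropy on training genes;
learning is transductive — test isoforms sit unlabeled in the graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Parameter, Tensor, segment_max_matrix

logger = logging.getLogger("isofuse")

EPS = 1e-7

__all__ = [
    "GraphSpec",
    "GCNConfig",
    "GCN",
    "ClassWeights",
    "build_adjacency",
    "normalize_adjacency",
    "gene_pool",
    "compute_class_weights",
    "wbce_loss",
    "train_gcn",
]


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


@dataclass
class GraphSpec:
    """Thresholded cosine-similarity graph and its normalized operator."""

    A: np.ndarray
    theta: float
    a: float
    A_norm: np.ndarray


def build_adjacency(X: np.ndarray, a: float = 10.0) -> GraphSpec:
    """Cosine-similarity graph keeping ~``a`` edges per node on average.

    The threshold θ is the (n·a)-th largest off-diagonal similarity,
    counting both ordered copies of each pair; entries at the threshold
    are all retained, so the graph stays symmetric. Zero rows have
    similarity 0 to everything by convention. The threshold is floored at
    zero: negative similarities are never kept, since the degree
    normalization requires nonnegative edge weights.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two isoforms to build a graph")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    off = S[~np.eye(n, dtype=bool)]
    k = int(round(n * a))
    if k > off.size:
        theta = float(off.min())
        logger.warning("n*a=%d exceeds %d off-diagonal entries; using min", k, off.size)
    elif k < 1:
        theta = float(off.max())
    else:
        theta = float(np.sort(off)[::-1][k - 1])
    if theta < 0.0:
        logger.warning("similarity threshold %.4f floored at 0", theta)
        theta = 0.0
    A = np.where(S >= theta, S, 0.0)
    np.fill_diagonal(A, 0.0)
    return GraphSpec(A=A, theta=theta, a=a, A_norm=normalize_adjacency(A))


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: P̄^{-1/2}(A+I)P̄^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    Abar = A + np.eye(A.shape[0])
    d = Abar.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return Abar * inv_sqrt[:, None] * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------


@dataclass
class GCNConfig:
    hidden: tuple = (256, 128, 64)  # three convolutional layers
    dropout: float = 0.5
    lrelu_slope: float = 0.2
    lr: float = 1e-3
    epochs: int = 300
    patience: int = 30
    a_edges: float = 10.0
    seed: int = 0


def _glorot(rng, d_in, d_out):
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


class GCN:
    """Three graph-convolutional layers plus a fully connected sigmoid head."""

    def __init__(self, d_in: int, n_terms: int, cfg: GCNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [d_in, *cfg.hidden]
        self.conv_W = [
            Parameter(_glorot(rng, dims[i], dims[i + 1])) for i in range(len(cfg.hidden))
        ]
        self.W_L = Parameter(_glorot(rng, dims[-1], n_terms))
        self.b_L = Parameter(np.zeros(n_terms))
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    @property
    def params(self):
        return [*self.conv_W, self.W_L, self.b_L]

    def forward(self, X, A_norm, training: bool = False) -> Tensor:
        """H_{l+1} = σ(Ã H_l W_l); Ŷ = sigmoid(H_L W_L + b_L).

        Dropout between convolutional layers in training mode only, so
        evaluation is deterministic.
        """
        A = A_norm if isinstance(A_norm, Tensor) else Tensor(A_norm)
        H = X if isinstance(X, Tensor) else Tensor(X)
        for li, W in enumerate(self.conv_W):
            H = (A @ H @ W).leaky_relu(self.cfg.lrelu_slope)
            if training and self.cfg.dropout > 0 and li < len(self.conv_W) - 1:
                keep = 1.0 - self.cfg.dropout
                mask = self._drop_rng.random(H.shape) < keep
                H = H * Tensor(mask / keep)
        Z = H @ self.W_L + self.b_L
        return Z.sigmoid()


# ---------------------------------------------------------------------------
# gene pooling and the weighted BCE objective
# ---------------------------------------------------------------------------


def gene_pool(yhat, seg_ids, n_genes: int):
    """Per-(gene, term) max over the gene's isoform scores.

    Accepts a tape Tensor (gradient flows to the argmax isoform) or a
    plain array.
    """
    if isinstance(yhat, Tensor):
        return yhat.segment_max(seg_ids, n_genes)
    return segment_max_matrix(np.asarray(yhat, dtype=np.float64), seg_ids, n_genes)


@dataclass
class ClassWeights:
    """Inverse-prevalence class weights per GO term, from training genes only."""

    w_pos: np.ndarray
    w_neg: np.ndarray
    active: np.ndarray = field(default=None)  # terms with >=1 positive and negative

    def __post_init__(self):
        if self.active is None:
            self.active = np.isfinite(self.w_pos) & np.isfinite(self.w_neg)


def compute_class_weights(Y_train: np.ndarray) -> ClassWeights:
    """w_pos[t] = genes / positive genes for t; w_neg analogous."""
    Y_train = np.asarray(Y_train, dtype=np.float64)
    g = Y_train.shape[0]
    npos = Y_train.sum(axis=0)
    nneg = g - npos
    with np.errstate(divide="ignore"):
        w_pos = np.where(npos > 0, g / np.maximum(npos, 1), np.inf)
        w_neg = np.where(nneg > 0, g / np.maximum(nneg, 1), np.inf)
    dropped = np.nonzero(npos == 0)[0]
    if dropped.size:
        warnings.warn(
            f"{dropped.size} terms have no positive training gene and are "
            "dropped from this view's loss",
            stacklevel=2,
        )
    return ClassWeights(w_pos=w_pos, w_neg=w_neg)


def wbce_loss(yhat_gene, Y, weights: ClassWeights):
    """Class-weighted BCE, mean over genes per term, summed over terms.

    Terms without both classes among training genes are excluded. Returns
    a tape Tensor when given one, else a float.
    """
    if np.any(weights.w_pos[weights.active] <= 0) or np.any(
        weights.w_neg[weights.active] <= 0
    ):
        raise ValueError("class weights must be positive")
    tape = isinstance(yhat_gene, Tensor)
    p = yhat_gene if tape else Tensor(np.asarray(yhat_gene, dtype=np.float64))
    Yt = Tensor(np.asarray(Y, dtype=np.float64))
    act = weights.active.astype(np.float64)
    wp = Tensor(np.where(weights.active, weights.w_pos, 0.0))
    wn = Tensor(np.where(weights.active, weights.w_neg, 0.0))
    pc = p.clip(EPS, 1.0 - EPS)
    per = Yt * pc.log() * wp + (1.0 - Yt) * (1.0 - pc).log() * wn
    loss = -(per.mean(axis=0) * Tensor(act)).sum() * (1.0 if act.any() else 0.0)
    return loss if tape else float(loss.data)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_gcn(X, A_norm, Y, seg_ids, split, cfg: GCNConfig):
    """Fit one omics-specific GCN transductively.

    ``Y`` is the gene x term label matrix; only training (and validation,
    for early stopping) gene rows are ever touched. Returns the trained
    model and its predictions for all isoforms.
    """
    n, n_terms = X.shape[0], Y.shape[1]
    model = GCN(X.shape[1], n_terms, cfg)
    weights = compute_class_weights(Y[split.train_genes])
    opt = Adam(model.params, lr=cfg.lr)
    Xt, At = Tensor(np.asarray(X, dtype=np.float64)), Tensor(np.asarray(A_norm))
    g = Y.shape[0]

    def loss_on(genes, training):
        yhat = model.forward(Xt, At, training=training)
        pooled = gene_pool(yhat, seg_ids, g)
        return wbce_loss(pooled.take_rows(genes), Y[genes], weights)

    best_val, best_state, bad = np.inf, None, 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        loss = loss_on(split.train_genes, training=True)
        loss.backward()
        opt.step()
        if len(split.val_genes):
            val = float(loss_on(split.val_genes, training=False).data)
            if val < best_val - 1e-9:
                best_val, bad = val, 0
                best_state = [p.data.copy() for p in model.params]
            else:
                bad += 1
                if bad >= cfg.patience:
                    logger.info("gcn early stop at epoch %d (val %.4f)", epoch, best_val)
                    break
    if best_state is not None:
        for p, s in zip(model.params, best_state):
            p.data = s
    yhat = model.forward(Xt, At, training=False)
    return model, np.asarray(yhat.data)
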