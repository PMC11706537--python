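"""Isoform-isoform interaction (III) generation.

A multi-input/multi-output autoencoder maps the three feature views of an
isoform — expression profile, sequence features and its gene's binary PPI
row — through shared interlayers to a common bottleneck, then decodes
symmetrically into three heads: reconstructed expression, reconstructed
sequence features, and an isoform-level interaction row (sigmoid, length
n). Only the input and output layers are view-specific; everything in
between is shared, so any view can be produced even when its input is
absent (zero-masked).

Training couples four objectives (the primary one plus one auxiliary
objective per masked view) with a cycle-consistency term and an
adversarial discriminator:

* generation — the predicted III matrix, max-pooled over each gene pair's
  isoform block, must reproduce the observed gene-level PPI (binary
  cross-entropy on the pooled block maxima; at least one isoform pair of
  an interacting gene pair must interact),
* reconstruction — mean squared error on expression and sequence,
* cycle consistency — outputs fed back through the autoencoder must
  recover the original inputs (L1); the generated III row re-enters the
  PPI input layer after max-pooling its columns back to gene level,
* adversarial — a three-layer discriminator separates real PPI rows from
  generated interaction rows (pooled to gene dimensions); the
  autoencoder is updated with the non-saturating generator loss.

The trained decoder's interaction head, symmetrized by an elementwise max
with its transpose and zeroed on the diagonal, is the III adjacency
handed to the prediction stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Parameter, Tensor

logger = logging.getLogger("isofuse")

EPS = 1e-7

__all__ = [
    "AEConfig",
    "Autoencoder",
    "Discriminator",
    "IIIMatrix",
    "loss_generation",
    "loss_reconstruction",
    "loss_cycle",
    "loss_total_primary",
    "loss_adversarial",
    "train_generator",
    "generate_iii",
    "symmetrize",
    "gene_ppi_matrix",
    "pool_iii_to_ppi",
]


@dataclass
class AEConfig:
    """Architecture and training knobs for the III generator."""

    input_dims: tuple = None  # (e, s, g); inferred from the bundle if None
    n_isoforms: int = None  # III head width; inferred if None
    shared_widths: tuple = (256, 128)
    bottleneck: int = 128
    lambdas: tuple = (3.0, 1.0, 1.0)  # generation, reconstruction, cycle
    adv_weight: float = 0.1
    use_auxiliary: bool = True
    lr: float = 1e-3
    epochs: int = 250
    batch: int = 0  # 0 = full batch; the gene-pair block max needs the
    # whole interaction matrix, so training is full-batch at desk scale
    dropout: float = 0.0  # optional hidden-layer dropout while training
    val_frac: float = 0.1
    patience: int = 60  # generation loss on a small gene subset is noisy
    disc_widths: tuple = (256, 64, 1)
    lrelu_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be nonnegative")


def _glorot(rng, d_in, d_out):
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


class Autoencoder:
    """Shared-core encoder/decoder with view-specific input/output layers."""

    def __init__(self, cfg: AEConfig):
        if cfg.input_dims is None or cfg.n_isoforms is None:
            raise ValueError("input_dims and n_isoforms must be set")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h0 = cfg.shared_widths[0]
        # view-specific input layers (projections into the first shared width)
        self.W_in = [Parameter(_glorot(rng, d, h0)) for d in cfg.input_dims]
        self.b_in = [Parameter(np.zeros(h0)) for _ in cfg.input_dims]
        # shared encoder chain down to the bottleneck
        enc_dims = [*cfg.shared_widths, cfg.bottleneck]
        self.enc_W = [
            Parameter(_glorot(rng, enc_dims[i], enc_dims[i + 1]))
            for i in range(len(enc_dims) - 1)
        ]
        self.enc_b = [Parameter(np.zeros(d)) for d in enc_dims[1:]]
        # shared decoder chain, symmetric to the encoder
        dec_dims = [cfg.bottleneck, *reversed(cfg.shared_widths)]
        self.dec_W = [
            Parameter(_glorot(rng, dec_dims[i], dec_dims[i + 1]))
            for i in range(len(dec_dims) - 1)
        ]
        self.dec_b = [Parameter(np.zeros(d)) for d in dec_dims[1:]]
        # view-specific output layers. Expression and sequence heads are
        # plain affine maps; the interaction head is relational: the output
        # row for isoform i has one entry per partner isoform j, computed as
        # a bilinear form of both isoforms' decoder representations, so the
        # head's width matches the III dimension n while the "column
        # weights" for partner j are P h_j rather than free parameters —
        # both endpoints contribute isoform-level information.
        hl = dec_dims[-1]
        self.W_out = [
            Parameter(_glorot(rng, hl, cfg.input_dims[0])),
            Parameter(_glorot(rng, hl, cfg.input_dims[1])),
        ]
        self.b_out = [
            Parameter(np.zeros(cfg.input_dims[0])),
            Parameter(np.zeros(cfg.input_dims[1])),
        ]
        self.P_iii = Parameter(_glorot(rng, hl, hl))
        self.b_iii = Parameter(np.zeros(1))
        self._drop_rng = np.random.default_rng(cfg.seed + 7)

    @property
    def params(self):
        return [
            *self.W_in,
            *self.b_in,
            *self.enc_W,
            *self.enc_b,
            *self.dec_W,
            *self.dec_b,
            *self.W_out,
            *self.b_out,
            self.P_iii,
            self.b_iii,
        ]

    def _dropout(self, h, training):
        if not training or self.cfg.dropout <= 0:
            return h
        keep = 1.0 - self.cfg.dropout
        mask = self._drop_rng.random(h.shape) < keep
        return h * Tensor(mask / keep)

    def forward(self, x1, x2, x3, input_mask=(1, 2, 3), training: bool = False,
                partner_h=None):
        """Run rows through the shared core; masked views are zero-filled.

        Returns ``(o1, o2, o3)`` with a sigmoid on the interaction head;
        ``o3[i, j]`` couples the decoder representations of isoforms i and
        j, with the full batch acting as the partner set unless
        ``partner_h`` overrides it. All shared parameters participate
        regardless of the mask. Dropout on the hidden activations applies
        in training mode only, so evaluation is deterministic.
        """
        slope = self.cfg.lrelu_slope
        xs = [Tensor._lift(x) for x in (x1, x2, x3)]
        h = None
        for k, x in enumerate(xs):
            if (k + 1) in input_mask:
                term = x @ self.W_in[k] + self.b_in[k]
            else:
                term = Tensor(np.zeros(x.shape[:-1] + (self.cfg.shared_widths[0],))) \
                    + self.b_in[k]
            h = term if h is None else h + term
        h = self._dropout(h.leaky_relu(slope), training)
        for W, b in zip(self.enc_W, self.enc_b):
            h = self._dropout((h @ W + b).leaky_relu(slope), training)
        for W, b in zip(self.dec_W, self.dec_b):
            h = self._dropout((h @ W + b).leaky_relu(slope), training)
        o1 = h @ self.W_out[0] + self.b_out[0]
        o2 = h @ self.W_out[1] + self.b_out[1]
        partner = partner_h if partner_h is not None else h
        o3 = (h @ self.P_iii @ partner.T + self.b_iii).sigmoid()
        return o1, o2, o3


class Discriminator:
    """Three stacked fully connected layers on gene-level interaction rows."""

    def __init__(self, d_in: int, widths=(256, 64, 1), slope: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [d_in, *widths]
        self.W = [Parameter(_glorot(rng, dims[i], dims[i + 1])) for i in range(len(widths))]
        self.b = [Parameter(np.zeros(d)) for d in widths]
        self.slope = slope

    @property
    def params(self):
        return [*self.W, *self.b]

    def forward(self, x) -> Tensor:
        h = Tensor._lift(x)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = h.leaky_relu(self.slope)
        return h.sigmoid()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _maybe_float(x: Tensor, tape: bool):
    return x if tape else float(x.data)


def gene_ppi_matrix(X3: np.ndarray, seg_ids: np.ndarray, n_genes: int) -> np.ndarray:
    """Recover the g x g gene PPI matrix from isoform-expanded rows."""
    rep = np.full(n_genes, -1, dtype=np.intp)
    for i, s in enumerate(seg_ids):
        if rep[s] < 0:
            rep[s] = i
    return np.asarray(X3, dtype=np.float64)[rep]


def pool_iii_to_ppi(O3, seg_ids, n_genes: int):
    """Max-pool an n x n interaction matrix's columns to gene level (n x g)."""
    if isinstance(O3, Tensor):
        return O3.T.segment_max(seg_ids, n_genes).T
    t = Tensor(np.asarray(O3, dtype=np.float64))
    return np.asarray(t.T.segment_max(seg_ids, n_genes).T.data)


def loss_generation(O3, X3, seg_ids, n_genes: int = None):
    """Gene-pair-max BCE between generated IIIs and observed PPIs.

    For each ordered gene pair (a, b), a != b, the maximum generated value
    over the a x b isoform block is compared against PPI(a, b); the result
    is the mean BCE over those gene pairs. Diagonal pairs are excluded.
    """
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    g = n_genes if n_genes is not None else int(seg_ids.max()) + 1
    if np.bincount(seg_ids, minlength=g).min() == 0:
        raise ValueError("every gene needs at least one isoform")
    tape = isinstance(O3, Tensor)
    O3t = O3 if tape else Tensor(np.asarray(O3, dtype=np.float64))
    P = O3t.segment_max(seg_ids, g).T.segment_max(seg_ids, g).T  # g x g block maxima
    ppi = gene_ppi_matrix(np.asarray(X3, dtype=np.float64), seg_ids, g)
    mask = ~np.eye(g, dtype=bool)
    pc = P.clip(EPS, 1.0 - EPS)
    bce = -(Tensor(ppi) * pc.log() + (1.0 - Tensor(ppi)) * (1.0 - pc).log())
    loss = (bce * Tensor(mask.astype(np.float64))).sum() * (1.0 / mask.sum())
    return _maybe_float(loss, tape)


def loss_reconstruction(O1, O2, X1, X2):
    """Sum of per-element MSE on the expression and sequence heads."""
    tape = isinstance(O1, Tensor) or isinstance(O2, Tensor)
    o1, o2 = Tensor._lift(O1), Tensor._lift(O2)
    loss = ((o1 - Tensor._lift(X1)) ** 2).mean() + ((o2 - Tensor._lift(X2)) ** 2).mean()
    return _maybe_float(loss, tape)


def _fit_loss(k: int, outs, X1, X2, X3, seg_ids, n_genes):
    """Per-view data-fit term: MSE for expression/sequence, pooled BCE for IIIs."""
    if k == 1:
        return ((outs[0] - Tensor._lift(X1)) ** 2).mean()
    if k == 2:
        return ((outs[1] - Tensor._lift(X2)) ** 2).mean()
    return Tensor._lift(loss_generation(outs[2], X3, seg_ids, n_genes))


def loss_cycle(ae: Autoencoder, outs, X1, X2, X3, seg_ids, n_genes: int,
               training: bool = False):
    """Second-pass L1: feed (o1, o2, pool(o3)) back and compare to the inputs.

    The generated interaction row is gene-max-pooled over columns so it
    fits the PPI input layer; the second-pass interaction output is pooled
    the same way before comparison with the original PPI rows.
    """
    o1, o2, o3 = (Tensor._lift(o) for o in outs)
    x3_back = pool_iii_to_ppi(o3, seg_ids, n_genes)
    r1, r2, r3 = ae.forward(o1, o2, x3_back, training=training)
    r3g = pool_iii_to_ppi(r3, seg_ids, n_genes)
    loss = (
        (r1 - Tensor._lift(X1)).abs().mean()
        + (r2 - Tensor._lift(X2)).abs().mean()
        + (r3g - Tensor._lift(X3)).abs().mean()
    )
    return loss


def loss_total_primary(ae: Autoencoder, X1, X2, X3, seg_ids, n_genes: int,
                       lambdas=(1.0, 1.0, 1.0), use_auxiliary: bool = True,
                       training: bool = False):
    """λ1·generation + λ2·reconstruction + λ3·cycle, plus the three
    auxiliary single-view-masked objectives when enabled.

    Each auxiliary objective masks one view's input, generates that view
    from the other two (its fit term takes the λ1 slot), reconstructs the
    remaining views (λ2 slot) and adds its own cycle term (λ3 slot).
    Returns ``(total, primary_outputs)``.
    """
    l1, l2, l3 = lambdas
    if any(l < 0 for l in lambdas):
        raise ValueError("lambdas must be nonnegative")

    def objective(mask, gen_view):
        outs = ae.forward(X1, X2, X3, input_mask=mask, training=training)
        rec_views = [k for k in (1, 2, 3) if k != gen_view]
        term = Tensor(0.0)
        if l1 > 0:
            term = term + l1 * _fit_loss(gen_view, outs, X1, X2, X3, seg_ids, n_genes)
        if l2 > 0:
            for k in rec_views:
                term = term + l2 * _fit_loss(k, outs, X1, X2, X3, seg_ids, n_genes)
        if l3 > 0:
            term = term + l3 * loss_cycle(ae, outs, X1, X2, X3, seg_ids, n_genes,
                                          training=training)
        return term, outs

    total, primary_outs = objective((1, 2, 3), gen_view=3)
    if use_auxiliary:
        for k in (1, 2, 3):
            mask = tuple(v for v in (1, 2, 3) if v != k)
            aux, _ = objective(mask, gen_view=k)
            total = total + aux
    return total, primary_outs


def loss_adversarial(o3_rows, x3_rows, disc: Discriminator):
    """Adversarial pair: minimax discriminator loss and the non-saturating
    generator loss.

    ``disc_loss`` is the negated minimax value −E[log D(x)] − E[log(1−D(o))]
    (its minimum over D parameters maximizes the objective); ``gen_loss``
    is −E[log D(o)].
    """
    tape = isinstance(o3_rows, Tensor)
    fake = Tensor._lift(o3_rows)
    real = Tensor._lift(x3_rows)
    d_real = disc.forward(real).clip(EPS, 1.0 - EPS)
    d_fake = disc.forward(fake).clip(EPS, 1.0 - EPS)
    disc_loss = -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    gen_loss = -d_fake.log().mean()
    return _maybe_float(gen_loss, tape), _maybe_float(disc_loss, tape)


# ---------------------------------------------------------------------------
# training and emission
# ---------------------------------------------------------------------------


@dataclass
class IIIMatrix:
    """Symmetric isoform x isoform interaction weights in [0, 1]."""

    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if not np.allclose(self.W, self.W.T):
            raise ValueError("III matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("III matrix must have zero diagonal")


def symmetrize(O3: np.ndarray) -> IIIMatrix:
    """Elementwise max with the transpose, diagonal forced to zero."""
    O3 = np.asarray(O3, dtype=np.float64)
    W = np.maximum(O3, O3.T)
    np.fill_diagonal(W, 0.0)
    return IIIMatrix(W=W)


def train_generator(bundle, cfg: AEConfig = None):
    """Train the III generator on a bundle; returns ``(ae, disc, history)``.

    Alternates one discriminator update and one autoencoder update per
    step; the autoencoder minimizes the four-objective total plus the
    (weighted) non-saturating adversarial term. Early stopping watches the
    generation loss on gene pairs touching a held-out validation gene
    subset. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AEConfig()
    n, g = bundle.n_isoforms, bundle.n_genes
    if cfg.input_dims is None:
        cfg.input_dims = (bundle.X1.shape[1], bundle.X2.shape[1], g)
    if cfg.n_isoforms is None:
        cfg.n_isoforms = n
    seg = bundle.gene_index_of_isoform
    ae = Autoencoder(cfg)
    disc = Discriminator(g, cfg.disc_widths, cfg.lrelu_slope, seed=cfg.seed + 1)
    opt_ae = Adam(ae.params, lr=cfg.lr)
    opt_d = Adam(disc.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 2)

    # held-out genes for early stopping on the generation loss
    n_val = max(1, int(round(cfg.val_frac * g)))
    val_genes = rng.choice(g, size=n_val, replace=False)
    val_mask = np.zeros((g, g), dtype=bool)
    val_mask[val_genes, :] = True
    val_mask[:, val_genes] = True
    np.fill_diagonal(val_mask, False)
    ppi = gene_ppi_matrix(bundle.X3, seg, g)

    X1, X2, X3 = (np.asarray(m, dtype=np.float64) for m in (bundle.X1, bundle.X2, bundle.X3))
    history = []
    best_val, best_state, bad = np.inf, None, 0

    def val_generation_loss():
        _, _, o3 = ae.forward(X1, X2, X3)
        P = np.asarray(
            Tensor(o3.data).segment_max(seg, g).T.segment_max(seg, g).T.data
        )
        pc = np.clip(P, EPS, 1.0 - EPS)
        bce = -(ppi * np.log(pc) + (1.0 - ppi) * np.log(1.0 - pc))
        return float(bce[val_mask].mean())

    for epoch in range(cfg.epochs):
        # ---- discriminator step (fake rows detached) --------------------
        _, _, o3 = ae.forward(X1, X2, X3)
        fake_rows = pool_iii_to_ppi(np.asarray(o3.data), seg, g)
        _, d_loss = loss_adversarial(Tensor(fake_rows), Tensor(X3), disc)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        # ---- autoencoder step ------------------------------------------
        total, outs = loss_total_primary(
            ae, X1, X2, X3, seg, g, cfg.lambdas, cfg.use_auxiliary, training=True
        )
        if cfg.adv_weight > 0:
            fake = pool_iii_to_ppi(outs[2], seg, g)
            gen_adv, _ = loss_adversarial(fake, Tensor(X3), disc)
            total = total + cfg.adv_weight * gen_adv
        opt_ae.zero_grad()
        total.backward()
        for p in disc.params:  # adversarial term must not move D here
            p.grad = None
        opt_ae.step()

        if not np.isfinite(float(total.data)):
            raise FloatingPointError(f"autoencoder loss diverged at epoch {epoch}")

        vloss = val_generation_loss()
        history.append({"epoch": epoch, "loss": float(total.data),
                        "disc_loss": float(d_loss.data), "val_gen_loss": vloss})
        logger.info("iii epoch %d total %.4f disc %.4f val_gen %.4f",
                    epoch, float(total.data), float(d_loss.data), vloss)
        if vloss < best_val - 1e-9:
            best_val, bad = vloss, 0
            best_state = [p.data.copy() for p in ae.params]
        else:
            bad += 1
            if bad >= cfg.patience:
                logger.info("iii generator early stop at epoch %d", epoch)
                break
    if best_state is not None:
        for p, s in zip(ae.params, best_state):
            p.data = s
    return ae, disc, history


def generate_iii(bundle, ae: Autoencoder) -> IIIMatrix:
    """Run the trained generator on the full bundle and symmetrize."""
    _, _, o3 = ae.forward(bundle.X1, bundle.X2, bundle.X3)
    return symmetrize(np.asarray(o3.data))
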