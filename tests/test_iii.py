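"""Generator forward pass, losses and training behavior."""

import numpy as np
import pytest

from isofuse import SynthConfig, generate
from isofuse._autodiff import Tensor
from isofuse.iii import (
    AEConfig,
    Autoencoder,
    Discriminator,
    IIIMatrix,
    gene_ppi_matrix,
    loss_adversarial,
    loss_cycle,
    loss_generation,
    loss_reconstruction,
    loss_total_primary,
    pool_iii_to_ppi,
    symmetrize,
    train_generator,
)

EPS = 1e-7


def tiny_ae(e=3, s=4, g=2, n=3, seed=0):
    cfg = AEConfig(input_dims=(e, s, g), n_isoforms=n, shared_widths=(6,),
                   bottleneck=4, seed=seed)
    return Autoencoder(cfg), cfg


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def test_zero_parameters_give_half_interaction_scores():
    """sigma(0) = 0.5 on the interaction head for an all-zero network."""
    ae, _ = tiny_ae()
    for p in ae.params:
        p.data[...] = 0.0
    _, _, o3 = ae.forward(np.ones((3, 3)), np.ones((3, 4)), np.ones((3, 2)))
    np.testing.assert_allclose(o3.data, 0.5)


def test_masking_is_zero_input_equivalence():
    """Masking view 3 equals feeding zeros through it, and perturbing a
    masked input never changes the outputs."""
    ae, _ = tiny_ae(seed=3)
    rng = np.random.default_rng(0)
    x1, x2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 4))
    zeros3 = np.zeros((3, 2))
    unmasked = ae.forward(x1, x2, zeros3, input_mask=(1, 2, 3))
    masked = ae.forward(x1, x2, rng.normal(size=(3, 2)), input_mask=(1, 2))
    for a, b in zip(unmasked, masked):
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


def test_forward_deterministic():
    ae, _ = tiny_ae(seed=5)
    rng = np.random.default_rng(1)
    args = (rng.normal(size=(3, 3)), rng.normal(size=(3, 4)), rng.normal(size=(3, 2)))
    o_a = ae.forward(*args)
    o_b = ae.forward(*args)
    for a, b in zip(o_a, o_b):
        np.testing.assert_array_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# generation loss (gene-pair block max)
# ---------------------------------------------------------------------------


def test_generation_loss_hand_example():
    """gA:{i1,i2}, gB:{i3}, PPI=1, best generated pair 0.9 -> -ln 0.9."""
    seg = np.array([0, 0, 1])
    O3 = np.array([[0.0, 0.0, 0.9],
                   [0.0, 0.0, 0.2],
                   [0.9, 0.2, 0.0]])
    X3 = np.array([[0.0, 1.0]] * 2 + [[1.0, 0.0]])
    val = loss_generation(O3, X3, seg, 2)
    assert val == pytest.approx(-np.log(0.9), abs=1e-9)
    assert val == pytest.approx(0.1054, abs=5e-4)


@pytest.mark.parametrize("target,score", [(1.0, 1.0 - EPS), (0.0, EPS)])
def test_generation_loss_fixed_points(target, score):
    seg = np.array([0, 1])
    O3 = np.full((2, 2), score)
    X3 = np.array([[0.0, target], [target, 0.0]])
    assert loss_generation(O3, X3, seg, 2) == pytest.approx(0.0, abs=1e-5)


def test_generation_loss_matches_brute_force_triple_loop():
    """Block-max aggregation agrees with an exhaustive scan of all isoform
    pairs per gene pair."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        g = rng.integers(2, 6)
        seg = np.sort(rng.integers(0, g, size=rng.integers(g, 25)))
        seg[:g] = np.arange(g)  # every gene keeps >= 1 isoform
        seg = np.sort(seg)
        n = len(seg)
        O3 = rng.random((n, n))
        ppi = (rng.random((g, g)) < 0.5).astype(float)
        ppi = np.triu(ppi, 1)
        ppi = ppi + ppi.T
        X3 = ppi[seg]
        expected, count = 0.0, 0
        for a in range(g):
            for b in range(g):
                if a == b:
                    continue
                block = [O3[i, j] for i in range(n) for j in range(n)
                         if seg[i] == a and seg[j] == b]
                p = np.clip(max(block), EPS, 1 - EPS)
                y = ppi[a, b]
                expected += -(y * np.log(p) + (1 - y) * np.log(1 - p))
                count += 1
        got = loss_generation(O3, X3, seg, g)
        assert got == pytest.approx(expected / count, rel=1e-9)


def test_generation_loss_empty_gene_raises():
    seg = np.array([0, 0])
    with pytest.raises(ValueError):
        loss_generation(np.full((2, 2), 0.5), np.zeros((2, 3)), seg, 3)


# ---------------------------------------------------------------------------
# reconstruction + cycle
# ---------------------------------------------------------------------------


def test_reconstruction_loss_values():
    assert loss_reconstruction(np.ones((2, 2)), np.ones((2, 3)),
                               np.ones((2, 2)), np.ones((2, 3))) == 0.0
    assert loss_reconstruction(np.array([[0.0]]), np.array([[2.0]]),
                               np.array([[1.0]]), np.array([[2.0]])) == 1.0
    base = loss_reconstruction(np.zeros((2, 2)), np.zeros((2, 2)),
                               np.ones((2, 2)), np.ones((2, 2)))
    scaled = loss_reconstruction(np.zeros((2, 2)), np.zeros((2, 2)),
                                 3 * np.ones((2, 2)), 3 * np.ones((2, 2)))
    assert scaled == pytest.approx(9 * base)


class _StubAE:
    """Second pass returns fixed outputs, shifted by delta."""

    def __init__(self, outs, delta=0.0):
        self._outs = outs
        self._delta = delta

    def forward(self, *args, **kwargs):
        return tuple(Tensor(o + self._delta) for o in self._outs)


def test_cycle_loss_zero_at_fixed_point_and_shift():
    rng = np.random.default_rng(2)
    seg = np.array([0, 0, 1])
    X1, X2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 4))
    X3 = np.array([[0.0, 1.0]] * 2 + [[1.0, 0.0]])
    O3 = X3[:, seg]  # pooling this back over columns reproduces X3
    stub = _StubAE((X1, X2, O3))
    outs = (Tensor(X1), Tensor(X2), Tensor(O3))
    assert float(loss_cycle(stub, outs, X1, X2, X3, seg, 2).data) == pytest.approx(0.0)
    delta = 0.25
    shifted = _StubAE((X1, X2, O3), delta=delta)
    # a constant +delta shift on every second-pass output gives L1 = 3*delta
    val = float(loss_cycle(shifted, outs, X1, X2, X3, seg, 2).data)
    assert val == pytest.approx(3 * delta, rel=1e-9)


def test_cycle_loss_matches_independent_two_pass_evaluation():
    """The tape value equals re-running the forward pass twice by hand."""
    ae, _ = tiny_ae(seed=9)
    rng = np.random.default_rng(3)
    seg = np.array([0, 0, 1])
    X1, X2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 4))
    X3 = np.array([[0.0, 1.0]] * 2 + [[1.0, 0.0]])
    outs = ae.forward(X1, X2, X3)
    got = float(loss_cycle(ae, outs, X1, X2, X3, seg, 2).data)
    o1, o2, o3 = (np.asarray(o.data) for o in outs)
    x3_back = pool_iii_to_ppi(o3, seg, 2)
    r1, r2, r3 = (np.asarray(o.data) for o in ae.forward(o1, o2, x3_back))
    r3g = pool_iii_to_ppi(r3, seg, 2)
    expected = (np.abs(r1 - X1).mean() + np.abs(r2 - X2).mean()
                + np.abs(r3g - X3).mean())
    assert got == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# total loss
# ---------------------------------------------------------------------------


def _loss_fixture():
    bundle, _, _ = generate(SynthConfig(n_genes=8, n_terms=4, e=5, s=6,
                                        n_latent=4, seed=17))
    cfg = AEConfig(input_dims=(5, 6, 8), n_isoforms=bundle.n_isoforms,
                   shared_widths=(8,), bottleneck=4, seed=1)
    return bundle, Autoencoder(cfg)


def test_total_loss_zero_lambdas_no_auxiliary():
    bundle, ae = _loss_fixture()
    seg = bundle.gene_index_of_isoform
    total, _ = loss_total_primary(ae, bundle.X1, bundle.X2, bundle.X3, seg,
                                  bundle.n_genes, lambdas=(0, 0, 0),
                                  use_auxiliary=False)
    assert float(total.data) == 0.0


def test_total_loss_lambda1_only_equals_generation_loss():
    bundle, ae = _loss_fixture()
    seg = bundle.gene_index_of_isoform
    total, outs = loss_total_primary(ae, bundle.X1, bundle.X2, bundle.X3, seg,
                                     bundle.n_genes, lambdas=(1, 0, 0),
                                     use_auxiliary=False)
    direct = loss_generation(np.asarray(outs[2].data), bundle.X3, seg, bundle.n_genes)
    assert float(total.data) == pytest.approx(direct, rel=1e-12)


def test_total_loss_is_linear_combination_of_components():
    bundle, ae = _loss_fixture()
    seg, g = bundle.gene_index_of_isoform, bundle.n_genes
    outs = ae.forward(bundle.X1, bundle.X2, bundle.X3)
    gen = loss_generation(np.asarray(outs[2].data), bundle.X3, seg, g)
    rec = loss_reconstruction(np.asarray(outs[0].data), np.asarray(outs[1].data),
                              bundle.X1, bundle.X2)
    cyc = float(loss_cycle(ae, outs, bundle.X1, bundle.X2, bundle.X3, seg, g).data)
    lam = (2.0, 3.0, 5.0)
    total, _ = loss_total_primary(ae, bundle.X1, bundle.X2, bundle.X3, seg, g,
                                  lambdas=lam, use_auxiliary=False)
    assert float(total.data) == pytest.approx(
        lam[0] * gen + lam[1] * rec + lam[2] * cyc, rel=1e-9)


def test_total_loss_rejects_negative_lambda():
    bundle, ae = _loss_fixture()
    with pytest.raises(ValueError):
        loss_total_primary(ae, bundle.X1, bundle.X2, bundle.X3,
                           bundle.gene_index_of_isoform, bundle.n_genes,
                           lambdas=(-1, 0, 0))


# ---------------------------------------------------------------------------
# adversarial loss
# ---------------------------------------------------------------------------


def test_adversarial_loss_at_uninformative_discriminator():
    """D == 0.5 gives the minimax value -(log .5 + log .5) = 2 ln 2."""
    disc = Discriminator(d_in=4, widths=(3, 3, 1), seed=0)
    for p in disc.params:
        p.data[...] = 0.0
    rng = np.random.default_rng(4)
    gen_loss, disc_loss = loss_adversarial(rng.random((5, 4)), rng.random((5, 4)), disc)
    assert disc_loss == pytest.approx(2 * np.log(2), rel=1e-12)
    assert gen_loss == pytest.approx(np.log(2), rel=1e-12)


def test_adversarial_loss_perfect_discriminator_limit():
    class _PerfectD:
        def forward(self, x):  # 1 on the first call (real), 0 on the second (fake)
            self.calls = getattr(self, "calls", 0) + 1
            v = 1.0 if self.calls == 1 else 0.0
            return Tensor(np.full((x.shape[0], 1), v))

    gen_loss, disc_loss = loss_adversarial(np.ones((3, 2)), np.ones((3, 2)), _PerfectD())
    assert disc_loss == pytest.approx(-2 * np.log(1 - EPS), abs=1e-6)  # maximal objective
    assert gen_loss == pytest.approx(-np.log(EPS), rel=1e-6)  # large


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------


def test_symmetrize_elementwise_max_and_zero_diagonal():
    W = symmetrize(np.array([[0.1, 0.9], [0.2, 0.3]])).W
    np.testing.assert_allclose(W, [[0.0, 0.9], [0.9, 0.0]])


def test_symmetrize_identity_on_symmetric_zero_diag_and_idempotent():
    rng = np.random.default_rng(5)
    A = rng.random((6, 6))
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    np.testing.assert_array_equal(symmetrize(A).W, A)
    once = symmetrize(rng.random((6, 6))).W
    np.testing.assert_array_equal(symmetrize(once).W, once)
    assert np.array_equal(once, once.T)


def test_iii_matrix_contract():
    with pytest.raises(ValueError):
        IIIMatrix(np.array([[0.0, 1.0], [0.5, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        IIIMatrix(np.array([[0.5]]))  # nonzero diagonal


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def train_bundle():
    bundle, _, _ = generate(SynthConfig(n_genes=20, n_terms=4, e=8, s=10,
                                        n_latent=4, signal=5.0, noise_sd=0.2,
                                        seed=19))
    return bundle


def test_train_generator_zero_epochs_returns_initial_params(train_bundle):
    cfg = AEConfig(shared_widths=(16,), bottleneck=8, epochs=0, seed=2)
    ae, _, history = train_generator(train_bundle, cfg)
    ref = Autoencoder(cfg)
    assert history == []
    for p, q in zip(ae.params, ref.params):
        np.testing.assert_array_equal(p.data, q.data)


def test_train_generator_descends_on_generation_loss(train_bundle):
    cfg = AEConfig(shared_widths=(16,), bottleneck=8, epochs=40, patience=40, seed=2)
    seg = train_bundle.gene_index_of_isoform
    ref = Autoencoder(AEConfig(input_dims=(8, 10, 20),
                               n_isoforms=train_bundle.n_isoforms,
                               shared_widths=(16,), bottleneck=8, epochs=0, seed=2))
    o3_init = np.asarray(ref.forward(train_bundle.X1, train_bundle.X2,
                                     train_bundle.X3)[2].data)
    init = loss_generation(o3_init, train_bundle.X3, seg, 20)
    ae, _, _ = train_generator(train_bundle, cfg)
    o3 = np.asarray(ae.forward(train_bundle.X1, train_bundle.X2,
                               train_bundle.X3)[2].data)
    final = loss_generation(o3, train_bundle.X3, seg, 20)
    assert final < init


def test_train_generator_deterministic(train_bundle):
    cfg = dict(shared_widths=(16,), bottleneck=8, epochs=5, seed=2)
    ae1, _, h1 = train_generator(train_bundle, AEConfig(**cfg))
    ae2, _, h2 = train_generator(train_bundle, AEConfig(**cfg))
    assert h1 == h2
    for p, q in zip(ae1.params, ae2.params):
        np.testing.assert_array_equal(p.data, q.data)


def test_gene_ppi_matrix_round_trip(train_bundle):
    seg = train_bundle.gene_index_of_isoform
    ppi = gene_ppi_matrix(train_bundle.X3, seg, train_bundle.n_genes)
    np.testing.assert_array_equal(ppi[seg], train_bundle.X3)
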