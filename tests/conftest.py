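"""Shared fixtures: synthetic datasets and (expensive) trained pipelines.

The benchmark fixture (150 genes, up to 3 isoforms per gene, 8 GO terms)
is trained once per seed and cached for the whole session, since several
tests inspect different facets of the same trained model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from isofuse import (
    AEConfig,
    GCNConfig,
    SynthConfig,
    TrainSchedule,
    build_adjacency,
    evaluate,
    generate,
    generate_iii,
    grouped_split,
    interaction_recovery_auroc,
    joint_train,
    train_gcn,
    train_generator,
)

BENCH_SEEDS = (7, 8, 9)


def make_benchmark(seed: int):
    """The standard study fixture: 150 genes, T=8, defaults."""
    return generate(SynthConfig(seed=seed))


@pytest.fixture(scope="session")
def bench7():
    bundle, ann, truth = make_benchmark(7)
    split = grouped_split(bundle, truth.homolog_groups, seed=7 + 11)
    return {"bundle": bundle, "ann": ann, "truth": truth, "split": split}


def run_full_pipeline(seed: int):
    """Generator + three single-view GCNs + joint model for one seed."""
    bundle, ann, truth = make_benchmark(seed)
    split = grouped_split(bundle, truth.homolog_groups, seed=seed + 11)
    seg = bundle.gene_index_of_isoform
    ae, _, history = train_generator(bundle, AEConfig(seed=seed + 23))
    iii = generate_iii(bundle, ae)
    iii_auroc = interaction_recovery_auroc(
        iii.W, truth.planted_iii, seg, split.test_genes
    )
    single = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, X in (("expr", bundle.X1), ("seq", bundle.X2), ("iii", iii.W)):
            cfg = GCNConfig(seed=seed + 31)
            gs = build_adjacency(np.asarray(X, dtype=np.float64), cfg.a_edges)
            _, pred = train_gcn(X, gs.A_norm, ann.Y, seg, split, cfg)
            single[name] = evaluate(pred, ann, seg, split.test_genes)
        from isofuse import VCDNConfig

        gcns, vcdn, final, info = joint_train(
            bundle, iii, ann, split,
            gcn_cfgs=[GCNConfig(seed=seed + 31 + k) for k in range(3)],
            vcdn_cfg=VCDNConfig(seed=seed + 47),
        )
    metrics = evaluate(final, ann, seg, split.test_genes)
    return {
        "seed": seed, "bundle": bundle, "ann": ann, "truth": truth,
        "split": split, "iii": iii, "iii_auroc": iii_auroc,
        "ae_history": history, "single": single, "final": final,
        "metrics": metrics, "info": info,
    }


@pytest.fixture(scope="session")
def full_runs():
    """Trained pipelines for the three benchmark seeds (slow, shared)."""
    return {seed: run_full_pipeline(seed) for seed in BENCH_SEEDS}


@pytest.fixture(scope="session")
def small_data():
    """A light fixture for fast structural tests."""
    cfg = SynthConfig(n_genes=40, n_terms=4, e=12, s=16, n_latent=4, seed=5)
    bundle, ann, truth = generate(cfg)
    split = grouped_split(bundle, truth.homolog_groups, seed=3)
    return {"cfg": cfg, "bundle": bundle, "ann": ann, "truth": truth, "split": split}


FAST_CONFIG = {
    "ae": {"shared_widths": (32,), "bottleneck": 16, "epochs": 20, "patience": 20},
    "gcn": {"hidden": (32, 16, 8), "epochs": 40, "patience": 40},
    "schedule": {"pretrain_epochs": 40, "joint_epochs": 8, "patience": 8},
}
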