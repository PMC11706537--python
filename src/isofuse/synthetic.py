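"""Synthetic multi-omics benchmark with planted isoform-level functions.

The generator plants a latent functional-module structure that induces the
three signals the integration pipeline exploits simultaneously:

* isoforms of one module are co-expressed (shared mean expression profile),
* they share sequence-feature prototypes,
* they preferentially interact (planted isoform-isoform interactions).

Each GO term is tied to one latent module, so isoform-level labels, gene
labels (OR-pooled over isoforms — a gene's annotation is explained by at
least one of its isoforms) and the planted interaction network are all
mutually consistent. Gene-level PPIs are derived from the planted
isoform-level interactions by a gene-pair OR, mirroring the rule the
generation loss uses in reverse. A fraction of genes is cloned into
two-gene homologous groups so the grouped splitter is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AnnotationSet, OmicsBundle

__all__ = ["SynthConfig", "GroundTruth", "generate"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give 150 genes with 1–3 isoforms each, 8 GO terms tied to 8
    latent modules, 30 expression samples, 40 sequence-feature dims,
    module effect size 3 against unit Gaussian noise, and a planted
    interaction probability of 0.8 within modules (background one tenth
    of that).
    """

    n_genes: int = 150
    iso_per_gene: tuple = (1, 3)  # inclusive uniform range
    n_terms: int = 8
    e: int = 30
    s: int = 40
    n_latent: int = 8
    signal: float = 3.0
    noise_sd: float = 1.0
    iii_density: float = 0.8
    background_frac: float = 0.1  # background edge rate = iii_density * this
    homolog_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_terms", "e", "s", "n_latent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("iii_density", "background_frac", "homolog_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < self.n_terms:
            raise ValueError("need n_genes >= n_terms so every term can be annotated")


@dataclass
class GroundTruth:
    """Planted isoform-level truth backing the generated files."""

    iso_labels: np.ndarray  # n x T binary
    gene_labels: np.ndarray  # g x T binary, OR over isoforms
    planted_iii: np.ndarray  # n x n symmetric binary, zero diagonal
    iso_modules: list  # module-index set per isoform
    module_of_term: np.ndarray  # T -> module index
    homolog_groups: dict = field(default_factory=dict)


def generate(cfg: SynthConfig):
    """Draw one synthetic dataset; deterministic given ``cfg.seed``.

    Returns ``(bundle, annotations, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.iso_per_gene

    # --- gene scaffold with homologous clone pairs -----------------------
    n_pairs = int(cfg.homolog_frac * cfg.n_genes / 2)
    gene_ids = [f"g{k:04d}" for k in range(cfg.n_genes)]
    homolog_groups = {}
    clone_of = {}  # clone gene index -> source gene index
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1  # adjacent genes form a clone pair
        clone_of[b] = a
        homolog_groups[gene_ids[a]] = f"hg{p:03d}"
        homolog_groups[gene_ids[b]] = f"hg{p:03d}"

    # --- module assignments ---------------------------------------------
    iso_ids, iso2gene, iso_modules = [], {}, []
    gene_iso_counts = rng.integers(lo, hi + 1, size=cfg.n_genes)
    gene_module_sets: list = [None] * cfg.n_genes
    for gidx in range(cfg.n_genes):
        if gidx in clone_of:  # homolog clone shares its partner's structure
            src = clone_of[gidx]
            gene_iso_counts[gidx] = gene_iso_counts[src]
            gene_module_sets[gidx] = gene_module_sets[src]
        else:
            sets = []
            for _ in range(gene_iso_counts[gidx]):
                k = rng.integers(1, min(3, cfg.n_latent) + 1)
                sets.append(tuple(sorted(rng.choice(cfg.n_latent, size=k, replace=False))))
            gene_module_sets[gidx] = sets
        for j, mods in enumerate(gene_module_sets[gidx]):
            iid = f"{gene_ids[gidx]}.i{j}"
            iso_ids.append(iid)
            iso2gene[iid] = gene_ids[gidx]
            iso_modules.append(set(mods))
    order = np.argsort(iso_ids)
    iso_ids = [iso_ids[k] for k in order]
    iso_modules = [iso_modules[k] for k in order]
    n = len(iso_ids)
    gidx = {g: k for k, g in enumerate(gene_ids)}
    seg = np.array([gidx[iso2gene[i]] for i in iso_ids], dtype=np.intp)

    # --- labels: one module per term, gene labels OR-pooled --------------
    module_of_term = np.arange(cfg.n_terms) % cfg.n_latent
    iso_labels = np.zeros((n, cfg.n_terms))
    for i, mods in enumerate(iso_modules):
        for t in range(cfg.n_terms):
            if module_of_term[t] in mods:
                iso_labels[i, t] = 1.0
    gene_labels = np.zeros((cfg.n_genes, cfg.n_terms))
    np.maximum.at(gene_labels, seg, iso_labels)

    # --- features: module means/prototypes + Gaussian noise --------------
    # expression means are half-normal so profiles are nonnegative (TPM-like)
    expr_means = np.abs(rng.normal(size=(cfg.n_latent, cfg.e)))
    seq_protos = rng.normal(size=(cfg.n_latent, cfg.s))
    X1 = np.zeros((n, cfg.e))
    X2 = np.zeros((n, cfg.s))
    for i, mods in enumerate(iso_modules):
        m = sorted(mods)
        X1[i] = cfg.signal * expr_means[m].mean(axis=0)
        X2[i] = cfg.signal * seq_protos[m].mean(axis=0)
    if cfg.noise_sd > 0:
        X1 += rng.normal(scale=cfg.noise_sd, size=X1.shape)
        X2 += rng.normal(scale=cfg.noise_sd, size=X2.shape)
    X1 = np.clip(X1, 0.0, None)

    # --- planted isoform-isoform interactions ----------------------------
    share = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            share[i, j] = share[j, i] = bool(iso_modules[i] & iso_modules[j])
    p_edge = np.where(share, cfg.iii_density, cfg.iii_density * cfg.background_frac)
    upper = np.triu(rng.random((n, n)) < p_edge, k=1)
    planted = (upper | upper.T).astype(np.float64)
    np.fill_diagonal(planted, 0.0)

    # --- gene-level PPI by OR over isoform pairs -------------------------
    row_pool = np.zeros((cfg.n_genes, n))
    np.maximum.at(row_pool, seg, planted)  # row_pool[a, j] = max_{i in a} III[i, j]
    ppi_g = np.zeros((cfg.n_genes, cfg.n_genes))
    np.maximum.at(ppi_g, seg, row_pool.T)  # ppi_g[b, a] = max_{j in b} row_pool[a, j]
    ppi_g = np.maximum(ppi_g, ppi_g.T)
    np.fill_diagonal(ppi_g, 0.0)
    X3 = ppi_g[seg]

    bundle = OmicsBundle(
        isoform_ids=iso_ids,
        gene_ids=gene_ids,
        iso2gene=iso2gene,
        X1=X1,
        X2=X2,
        X3=X3,
    )
    ann = AnnotationSet(term_ids=[f"GO:{t:07d}" for t in range(cfg.n_terms)], Y=gene_labels)
    truth = GroundTruth(
        iso_labels=iso_labels,
        gene_labels=gene_labels,
        planted_iii=planted,
        iso_modules=iso_modules,
        module_of_term=module_of_term,
        homolog_groups=homolog_groups,
    )
    return bundle, ann, truth
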