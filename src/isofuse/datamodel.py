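"""Data model and file IO for isoform function prediction.

All interchange files are tab-separated UTF-8 text with the identifier in
the first column. The central container is :class:`OmicsBundle`, which
aligns three feature views on a canonical (sorted) isoform order:

* ``X1`` — expression (isoforms x samples, nonnegative, TPM-like),
* ``X2`` — sequence features (isoforms x s real-valued embedding dims),
* ``X3`` — binary protein interactions (isoforms x genes), where every
  isoform inherits the interaction row of its parent gene.

Gene-level GO annotations live in :class:`AnnotationSet`; train/test
partitions that never separate isoforms of one gene, nor genes of one
homologous group, live in :class:`SplitSpec`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("isofuse")

__all__ = [
    "OmicsBundle",
    "AnnotationSet",
    "SplitSpec",
    "load_bundle",
    "write_bundle",
    "load_annotations",
    "load_homolog_groups",
    "filter_terms",
    "grouped_split",
    "tissue_enhanced_subnetwork",
    "write_predictions",
    "load_predictions",
]


class AlignmentError(ValueError):
    """Feature files disagree on their isoform rows."""


class MappingError(ValueError):
    """An isoform is missing from the isoform->gene map."""


class FormatError(ValueError):
    """A file violates the documented TSV dialect."""


class InfeasibleSplitError(ValueError):
    """A single linked group is too large for the requested split."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsBundle:
    """Aligned multi-omics feature views over one set of isoforms."""

    isoform_ids: list
    gene_ids: list
    iso2gene: dict
    X1: np.ndarray  # n x e expression
    X2: np.ndarray  # n x s sequence features
    X3: np.ndarray  # n x g binary gene-level interactions

    def __post_init__(self):
        self.validate()

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def gene_index_of_isoform(self) -> np.ndarray:
        """Integer gene index per isoform row (the segment-id vector)."""
        gidx = {g: j for j, g in enumerate(self.gene_ids)}
        return np.array([gidx[self.iso2gene[i]] for i in self.isoform_ids], dtype=np.intp)

    def isoforms_of_gene(self, gene) -> np.ndarray:
        return np.array(
            [k for k, i in enumerate(self.isoform_ids) if self.iso2gene[i] == gene],
            dtype=np.intp,
        )

    def validate(self) -> None:
        n, g = len(self.isoform_ids), len(self.gene_ids)
        if len(set(self.isoform_ids)) != n or len(set(self.gene_ids)) != g:
            raise FormatError("duplicate isoform or gene identifiers")
        if not (n >= g >= 1):
            raise AlignmentError(f"need n >= g >= 1, got n={n}, g={g}")
        for X, name in ((self.X1, "X1"), (self.X2, "X2"), (self.X3, "X3")):
            if X.shape[0] != n:
                raise AlignmentError(f"{name} has {X.shape[0]} rows, expected {n}")
        if self.X3.shape[1] != g:
            raise AlignmentError("X3 column count does not match gene count")
        if not np.isin(self.X3, (0.0, 1.0)).all():
            raise FormatError("X3 must be binary")
        missing = [i for i in self.isoform_ids if i not in self.iso2gene]
        if missing:
            raise MappingError(f"isoforms missing from map: {missing[:5]}")
        # all isoforms of one gene share the gene's interaction row
        seg = self.gene_index_of_isoform
        for j in range(g):
            rows = self.X3[seg == j]
            if rows.shape[0] and not (rows == rows[0]).all():
                raise FormatError(
                    f"isoforms of gene {self.gene_ids[j]} carry different PPI rows"
                )


@dataclass
class AnnotationSet:
    """Binary gene x GO-term label matrix with per-term sizes."""

    term_ids: list
    Y: np.ndarray  # g x T
    term_size: np.ndarray = field(default=None)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise FormatError("annotation matrix must be binary")
        if self.Y.shape[1] != len(self.term_ids):
            raise AlignmentError("term count does not match Y columns")
        self.term_size = self.Y.sum(axis=0).astype(np.intp)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)


@dataclass
class SplitSpec:
    """Disjoint isoform index sets respecting gene and homolog grouping."""

    train_iso: np.ndarray
    val_iso: np.ndarray
    test_iso: np.ndarray
    train_genes: np.ndarray
    val_genes: np.ndarray
    test_genes: np.ndarray
    homolog_groups: dict = field(default_factory=dict)

    def __post_init__(self):
        sets = [set(self.train_iso), set(self.val_iso), set(self.test_iso)]
        for a in range(3):
            for b in range(a + 1, 3):
                if sets[a] & sets[b]:
                    raise ValueError("split index sets overlap")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row identifiers")
    return df


def load_bundle(expr_path, seq_path, ppi_path, map_path) -> OmicsBundle:
    """Read the four input files and assemble a validated bundle.

    The gene-level PPI edge list is expanded to an isoform x gene binary
    matrix: each isoform inherits the full interaction row of its gene.
    Edges touching genes with no isoform in the feature files are dropped
    with a warning. Isoform order is canonicalized by sorting identifiers.
    """
    expr = _read_matrix_tsv(expr_path)
    seq = _read_matrix_tsv(seq_path)
    iso_map = pd.read_csv(map_path, sep="\t", header=0)
    if iso_map.shape[1] < 2:
        raise FormatError("map file needs (isoform, gene) columns")
    iso2gene = dict(zip(iso_map.iloc[:, 0].astype(str), iso_map.iloc[:, 1].astype(str)))

    if set(expr.index) != set(seq.index):
        raise AlignmentError("expression and sequence files list different isoforms")
    isoform_ids = sorted(str(i) for i in expr.index)
    missing = [i for i in isoform_ids if i not in iso2gene]
    if missing:
        raise MappingError(f"isoforms absent from map: {missing[:5]}")

    gene_ids = sorted({iso2gene[i] for i in isoform_ids})
    gidx = {g: j for j, g in enumerate(gene_ids)}

    edges = pd.read_csv(ppi_path, sep="\t", header=0)
    ppi_g = np.zeros((len(gene_ids), len(gene_ids)))
    n_dropped = 0
    for a, b in zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)):
        if a in gidx and b in gidx:
            ppi_g[gidx[a], gidx[b]] = 1.0
            ppi_g[gidx[b], gidx[a]] = 1.0
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d PPI edges touching genes with no isoforms", n_dropped)

    expr = expr.loc[isoform_ids]
    seq = seq.loc[isoform_ids]
    X3 = np.stack([ppi_g[gidx[iso2gene[i]]] for i in isoform_ids])
    return OmicsBundle(
        isoform_ids=isoform_ids,
        gene_ids=gene_ids,
        iso2gene={i: iso2gene[i] for i in isoform_ids},
        X1=expr.to_numpy(dtype=np.float64),
        X2=seq.to_numpy(dtype=np.float64),
        X3=X3,
    )


def write_bundle(bundle: OmicsBundle, outdir) -> dict:
    """Write the bundle back to the four TSV inputs; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, f"{k}.tsv") for k in ("expr", "seq", "ppi", "map")}
    pd.DataFrame(
        bundle.X1,
        index=pd.Index(bundle.isoform_ids, name="isoform"),
        columns=[f"sample_{j}" for j in range(bundle.X1.shape[1])],
    ).to_csv(paths["expr"], sep="\t")
    pd.DataFrame(
        bundle.X2,
        index=pd.Index(bundle.isoform_ids, name="isoform"),
        columns=[f"feat_{j}" for j in range(bundle.X2.shape[1])],
    ).to_csv(paths["seq"], sep="\t")
    # recover the gene-level edge list from any representative isoform row
    seg = bundle.gene_index_of_isoform
    rep = {}
    for k, j in enumerate(seg):
        rep.setdefault(j, k)
    rows = []
    for j, g in enumerate(bundle.gene_ids):
        row = bundle.X3[rep[j]]
        for m in np.nonzero(row)[0]:
            if m >= j:
                rows.append((g, bundle.gene_ids[m]))
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        paths["ppi"], sep="\t", index=False
    )
    pd.DataFrame(
        {"isoform": bundle.isoform_ids, "gene": [bundle.iso2gene[i] for i in bundle.isoform_ids]}
    ).to_csv(paths["map"], sep="\t", index=False)
    return paths


def load_annotations(ann_path, gene_ids) -> AnnotationSet:
    """Read (gene, term) pairs and build the gene x term binary matrix.

    Rows follow ``gene_ids``; annotations for unknown genes are ignored.
    Term order is canonical (sorted).
    """
    df = pd.read_csv(ann_path, sep="\t", header=0)
    gidx = {g: j for j, g in enumerate(gene_ids)}
    term_ids = sorted(df.iloc[:, 1].astype(str).unique())
    tidx = {t: j for j, t in enumerate(term_ids)}
    Y = np.zeros((len(gene_ids), len(term_ids)))
    for g, t in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if g in gidx:
            Y[gidx[g], tidx[t]] = 1.0
    return AnnotationSet(term_ids=term_ids, Y=Y)


def load_homolog_groups(path) -> dict:
    """Read a two-column (gene, group_id) TSV into {gene: group_id}."""
    df = pd.read_csv(path, sep="\t", header=0)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# GO-term filtering
# ---------------------------------------------------------------------------


def filter_terms(ann: AnnotationSet, min_size: int = 5, max_size: int = 1000) -> AnnotationSet:
    """Drop GO terms that are too specific or too general.

    Keeps exactly the terms with ``min_size <= size <= max_size`` annotated
    genes (the defaults drop size < 5 and size > 1000), preserving column
    order. Idempotent.
    """
    if not (0 < min_size <= max_size):
        raise ValueError("need 0 < min_size <= max_size")
    keep = (ann.term_size >= min_size) & (ann.term_size <= max_size)
    if not keep.any():
        warnings.warn("term-size filter removed every GO term", stacklevel=2)
    return AnnotationSet(
        term_ids=[t for t, k in zip(ann.term_ids, keep) if k],
        Y=ann.Y[:, keep],
    )


# ---------------------------------------------------------------------------
# grouped train/val/test split
# ---------------------------------------------------------------------------


def grouped_split(
    bundle: OmicsBundle,
    homolog_groups: dict | None = None,
    test_frac: float = 0.2,
    val_frac: float = 0.1,
    seed: int = 0,
) -> SplitSpec:
    """Partition isoforms so no gene or homologous group straddles the split.

    Splitting operates on linked groups of genes (a homolog group, or a
    singleton for ungrouped genes); isoforms follow their gene. ``val_frac``
    of training genes form a validation subset, also group-respecting.
    Deterministic given ``seed``; gene fractions are met within one group.
    """
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")
    homolog_groups = homolog_groups or {}
    g = bundle.n_genes
    groups: dict = {}
    for gene in bundle.gene_ids:
        key = ("H", homolog_groups[gene]) if gene in homolog_groups else ("S", gene)
        groups.setdefault(key, []).append(gene)
    sizes = {k: len(v) for k, v in groups.items()}
    largest = max(sizes.values())
    if largest > max(test_frac, 1.0 - test_frac) * g:
        raise InfeasibleSplitError(
            f"a linked group of {largest} genes cannot fit either split side"
        )

    rng = np.random.default_rng(seed)
    keys = sorted(groups.keys())
    rng.shuffle(keys)
    target_test = test_frac * g
    test_genes: list = []
    train_side: list = []
    count = 0
    for k in keys:
        # fill test greedily; overshoot is bounded by one group
        if count < target_test:
            test_genes.extend(groups[k])
            count += sizes[k]
        else:
            train_side.append(k)
    # validation: group-respecting subset of the training side
    n_train_genes = g - count
    target_val = val_frac * n_train_genes
    val_genes: list = []
    train_genes: list = []
    vcount = 0
    for k in train_side:
        if vcount < target_val:
            val_genes.extend(groups[k])
            vcount += sizes[k]
        else:
            train_genes.extend(groups[k])

    def iso_idx(genes):
        gs = set(genes)
        return np.array(
            [k for k, i in enumerate(bundle.isoform_ids) if bundle.iso2gene[i] in gs],
            dtype=np.intp,
        )

    gidx = {gn: j for j, gn in enumerate(bundle.gene_ids)}

    def gene_idx(genes):
        return np.array(sorted(gidx[gn] for gn in genes), dtype=np.intp)

    return SplitSpec(
        train_iso=iso_idx(train_genes),
        val_iso=iso_idx(val_genes),
        test_iso=iso_idx(test_genes),
        train_genes=gene_idx(train_genes),
        val_genes=gene_idx(val_genes),
        test_genes=gene_idx(test_genes),
        homolog_groups=homolog_groups,
    )


# ---------------------------------------------------------------------------
# tissue-enhanced PPI subnetworks
# ---------------------------------------------------------------------------


def tissue_enhanced_subnetwork(
    expr_by_tissue: pd.DataFrame, ppi_edges, tissue: str, fold: float = 4.0
) -> list:
    """Extract the PPI edges anchored at tissue-enhanced genes.

    A gene is tissue-enhanced when its mean expression in ``tissue`` is at
    least ``fold`` times its mean across the other tissues (4-fold for
    major tissues, 2-fold for brain sub-tissues). An edge is retained when
    at least one endpoint is enhanced.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if tissue not in expr_by_tissue.columns:
        raise KeyError(f"tissue {tissue!r} not in expression summary")
    target = expr_by_tissue[tissue]
    others = expr_by_tissue.drop(columns=[tissue]).mean(axis=1)
    enhanced = set(expr_by_tissue.index[target >= fold * others].astype(str))
    return [
        (str(a), str(b))
        for a, b in ppi_edges
        if str(a) in enhanced or str(b) in enhanced
    ]


# ---------------------------------------------------------------------------
# prediction IO
# ---------------------------------------------------------------------------


def write_predictions(scores: np.ndarray, isoform_ids, term_ids, path) -> None:
    """Write an isoform x term score matrix as TSV, 6 decimal places."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("prediction scores must lie in [0, 1]")
    pd.DataFrame(
        scores, index=pd.Index(isoform_ids, name="isoform"), columns=term_ids
    ).to_csv(path, sep="\t", float_format="%.6f")


def load_predictions(path):
    """Read a prediction TSV back into (scores, isoform_ids, term_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.index.astype(str)), list(df.columns)
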