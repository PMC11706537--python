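"""Gene-level evaluation of isoform function predictions.

For each GO term, isoform scores are pooled to their gene by max (the
best-scoring isoform explains the gene's annotation) and compared with
the binary gene labels of the held-out test genes. Per-term AUC uses the
midpoint-rank tie convention; AUPRC is step-wise average precision
(no trapezoidal interpolation). Terms whose test labels are single-class
are excluded from the medians. A within-gene concordance statistic
measures isoform-level disambiguation on multi-isoform genes, which the
gene-level AUC cannot see.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .gcn import gene_pool

logger = logging.getLogger("isofuse")

DEFAULT_SIZE_BINS = ((10, 150), (151, 300), (301, 600), (601, 1000))

__all__ = [
    "evaluate",
    "size_category_report",
    "within_gene_concordance",
    "interaction_recovery_auroc",
    "DEFAULT_SIZE_BINS",
]


def evaluate(pred: np.ndarray, ann, seg_ids, test_genes) -> pd.DataFrame:
    """Per-term gene-level AUC/AUPRC on test genes, with medians attached.

    Returns a DataFrame with one row per term (``term``, ``term_size``,
    ``auc``, ``auprc``, ``n_pos``, ``n_test``); the medians over terms
    with both classes present are stored in ``df.attrs["median_auc"]``
    and ``df.attrs["median_auprc"]``.
    """
    test_genes = np.asarray(test_genes, dtype=np.intp)
    pooled = gene_pool(np.asarray(pred, dtype=np.float64), seg_ids, ann.Y.shape[0])
    rows = []
    for t, term in enumerate(ann.term_ids):
        y = ann.Y[test_genes, t]
        s = pooled[test_genes, t]
        if y.min() == y.max():
            logger.info("term %s has single-class test labels; excluded", term)
            auc = auprc = np.nan
        else:
            auc = roc_auc_score(y, s)
            auprc = average_precision_score(y, s)
        rows.append(
            {"term": term, "term_size": int(ann.term_size[t]), "auc": auc,
             "auprc": auprc, "n_pos": int(y.sum()), "n_test": len(test_genes)}
        )
    df = pd.DataFrame(rows)
    df.attrs["median_auc"] = float(np.nanmedian(df["auc"])) if df["auc"].notna().any() else np.nan
    df.attrs["median_auprc"] = (
        float(np.nanmedian(df["auprc"])) if df["auprc"].notna().any() else np.nan
    )
    return df


def size_category_report(
    pred: np.ndarray,
    ann,
    seg_ids,
    test_genes,
    size_bins=DEFAULT_SIZE_BINS,
    branch_map: dict | None = None,
) -> pd.DataFrame:
    """Median AUC/AUPRC by term-size bin (and GO branch), split by gene class.

    Gene classes are single-isoform genes (SIG), multi-isoform genes (MIG)
    and all test genes; each class is evaluated on its own gene subset.
    Empty groups yield rows with null metrics.
    """
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    test_genes = np.asarray(test_genes, dtype=np.intp)
    iso_counts = np.bincount(seg_ids, minlength=ann.Y.shape[0])
    subsets = {
        "all": test_genes,
        "SIG": test_genes[iso_counts[test_genes] == 1],
        "MIG": test_genes[iso_counts[test_genes] > 1],
    }
    groupings = [("size", f"[{lo},{hi}]",
                  np.array([lo <= sz <= hi for sz in ann.term_size]))
                 for lo, hi in size_bins]
    if branch_map:
        for branch in sorted(set(branch_map.values())):
            sel = np.array([branch_map.get(t) == branch for t in ann.term_ids])
            groupings.append(("branch", branch, sel))

    rows = []
    for subset_name, genes in subsets.items():
        if len(genes):
            df = evaluate(pred, ann, seg_ids, genes)
        else:
            df = None
        for kind, label, sel in groupings:
            if df is None or not sel.any():
                auc = auprc = np.nan
                n_terms = int(sel.sum())
            else:
                auc = float(np.nanmedian(df.loc[sel, "auc"])) if df.loc[sel, "auc"].notna().any() else np.nan
                auprc = float(np.nanmedian(df.loc[sel, "auprc"])) if df.loc[sel, "auprc"].notna().any() else np.nan
                n_terms = int(sel.sum())
            rows.append({"grouping": kind, "group": label, "subset": subset_name,
                         "n_terms": n_terms, "median_auc": auc, "median_auprc": auprc})
    return pd.DataFrame(rows)


def within_gene_concordance(pred, iso_labels, seg_ids, iso_subset=None) -> float:
    """Isoform-level discrimination inside multi-isoform genes.

    Over all (functional, non-functional) isoform pairs belonging to the
    same gene (and the same term), returns the fraction where the
    functional isoform scores strictly higher, counting ties as half —
    the within-gene analogue of AUC. Pairs where the gene's isoforms are
    single-class for the term contribute nothing. Returns NaN if no
    informative pair exists.
    """
    pred = np.asarray(pred, dtype=np.float64)
    iso_labels = np.asarray(iso_labels, dtype=np.float64)
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    idx = np.arange(pred.shape[0]) if iso_subset is None else np.asarray(iso_subset)
    conc, total = 0.0, 0
    for gidx in np.unique(seg_ids[idx]):
        members = idx[seg_ids[idx] == gidx]
        if len(members) < 2:
            continue
        for t in range(pred.shape[1]):
            pos = members[iso_labels[members, t] == 1]
            neg = members[iso_labels[members, t] == 0]
            for i in pos:
                for j in neg:
                    total += 1
                    if pred[i, t] > pred[j, t]:
                        conc += 1.0
                    elif pred[i, t] == pred[j, t]:
                        conc += 0.5
    return conc / total if total else np.nan


def interaction_recovery_auroc(W, planted, seg_ids, gene_subset=None) -> float:
    """AUROC of generated interaction weights against the planted truth.

    Scored over unordered cross-gene isoform pairs; ``gene_subset``
    restricts both endpoints (e.g. to test genes).
    """
    W = np.asarray(W, dtype=np.float64)
    planted = np.asarray(planted, dtype=np.float64)
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = seg_ids[iu] != seg_ids[ju]
    if gene_subset is not None:
        inset = np.zeros(seg_ids.max() + 1, dtype=bool)
        inset[np.asarray(gene_subset, dtype=np.intp)] = True
        keep &= inset[seg_ids[iu]] & inset[seg_ids[ju]]
    return float(roc_auc_score(planted[iu[keep], ju[keep]], W[iu[keep], ju[keep]]))
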