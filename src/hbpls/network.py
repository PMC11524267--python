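"""Regulator ranking and evaluation against known positives.

A fitted HB-PLS model carries a p x q coefficient matrix A mapping TFs to
pathway genes.  A TF's *connectivity* summarizes its association strength
across the pathway: by default the L1 norm of its row of A; the count of
nonzero targets is available as an alternative.  Rankings are evaluated
against a literature-supported positive set via ROC curves and the area
under them (AuROC), which equals the probability that a randomly chosen
known regulator outranks a randomly chosen non-regulator (ties count 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "RegulatorRanking",
    "ROCResult",
    "rank_regulators",
    "roc_auc",
    "per_gene_recovery",
    "export_edges",
]


@dataclass
class RegulatorRanking:
    """Ordered TF scores: columns tf_id, score, rank (1-based, contiguous)."""

    table: pd.DataFrame
    scoring: str  # "l1" or "nonzero_count"

    @property
    def tf_ids(self) -> list[str]:
        return self.table["tf_id"].tolist()


@dataclass
class ROCResult:
    """ROC curve points and the area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_positives: int
    n_negatives: int


def _connectivity(A: np.ndarray, scoring: str) -> np.ndarray:
    if scoring == "l1":
        return np.sum(np.abs(A), axis=1)
    if scoring == "nonzero_count":
        return np.sum(A != 0, axis=1).astype(float)
    raise ValueError(f"unknown scoring rule {scoring!r}")


def rank_regulators(model, top_n: int | None = None, scoring: str = "l1") -> RegulatorRanking:
    """Rank TFs by connectivity with the pathway genes.

    Sorting is descending by score with ties broken stably by input gene
    order, so rankings are reproducible.
    """
    scores = _connectivity(model.A, scoring)
    if not np.any(scores):
        warnings.warn("all coefficients are zero; empty ranking", RuntimeWarning, stacklevel=2)
        return RegulatorRanking(
            table=pd.DataFrame(columns=["tf_id", "score", "rank"]), scoring=scoring
        )
    order = np.argsort(-scores, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    table = pd.DataFrame(
        {
            "tf_id": [model.tf_ids[j] for j in order],
            "score": scores[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return RegulatorRanking(table=table, scoring=scoring)


def roc_auc(scores, ids, positives) -> ROCResult:
    """ROC curve and AuROC of a score vector against a known-positive id set.

    AuROC is computed from midranks (the Mann-Whitney statistic), so tied
    scores contribute 1/2; the curve itself sweeps distinct score values.
    """
    scores = np.asarray(scores, dtype=float)
    ids = list(ids)
    if len(ids) != scores.shape[0]:
        raise ValueError("scores and ids must have equal length")
    positives = set(positives)
    labels = np.array([1 if g in positives else 0 for g in ids])
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative among scored genes")

    ranks = rankdata(scores)  # midranks handle ties as 1/2 wins
    auroc = (float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(fpr=fpr, tpr=tpr, auroc=float(auroc), n_positives=n_pos, n_negatives=n_neg)


def per_gene_recovery(model, gene_id: str, positives, cutoffs=range(1, 41)) -> np.ndarray:
    """Known positives among the top-c TFs for one pathway gene, per cutoff c.

    TFs are ranked by |A_jk| for the requested pathway gene; for each cutoff
    the count of known positives in the top-c list is returned.  Counts are
    nondecreasing in c because top-c lists are nested.
    """
    try:
        k = model.gene_ids.index(gene_id)
    except ValueError:
        raise KeyError(f"unknown pathway gene id {gene_id!r}") from None
    positives = set(positives)
    col = np.abs(model.A[:, k])
    order = np.argsort(-col, kind="stable")
    # ignore exact zeros: a zero coefficient is "not identified"
    order = [j for j in order if col[j] > 0]
    hits = np.array([1 if model.tf_ids[j] in positives else 0 for j in order])
    counts = np.concatenate([[0], np.cumsum(hits)])
    return np.array([counts[min(c, len(order))] for c in cutoffs])


def export_edges(model, threshold: float = 0.0) -> pd.DataFrame:
    """All (TF, pathway gene) pairs with |A_jk| >= threshold, strongest first.

    Exact zeros are never exported.  Columns: tf_id, target_id, coefficient.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    A = model.A
    jj, kk = np.nonzero(np.abs(A) >= max(threshold, np.finfo(float).tiny))
    coefs = A[jj, kk]
    order = np.argsort(-np.abs(coefs), kind="stable")
    return pd.DataFrame(
        {
            "tf_id": [model.tf_ids[j] for j in jj[order]],
            "target_id": [model.gene_ids[k] for k in kk[order]],
            "coefficient": coefs[order],
        }
    )
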