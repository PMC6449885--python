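"""Leave-one-out cross-validation, pooled ROC, and cold-start evaluation.

Each known association (i, j) is deleted in turn; the score column for
disease j is recomputed and the held-out miRNA is ranked among the
candidate miRNAs (those with no verified association to j, plus i).
The ROC pools a rank cutoff across folds: at cutoff c a fold's top
min(c, n) predictions are called positive, the held-out pair is the
fold's single true positive, and TP/FP/TN/FN are summed over folds
(TPR = TP/(TP+FN), FPR = FP/(TN+FP)); the AUC is the trapezoidal
integral of the pooled curve.

Similarity networks are computed once, outside the loop: they depend on
the interaction / family / cluster / DAG data only, never on the
association matrix, so no information about the held-out pair leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AssociationMatrix, BinaryRelationMatrix
from .prediction import Scorer
from .similarity import Params

__all__ = [
    "ROCResult",
    "FoldRecord",
    "CVReport",
    "confusion_rates",
    "pooled_roc",
    "mann_whitney_auc",
    "loocv",
    "isolated_disease_eval",
    "isolated_mirna_eval",
    "parameter_grid",
    "permute_associations",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray  # rank cutoffs, starting at 0
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
            }
        )


@dataclass
class FoldRecord:
    mirna: str
    disease: str
    rank: int
    n_candidates: int


@dataclass
class CVReport:
    roc: ROCResult
    per_disease_auc: dict[str, float]
    folds: list[FoldRecord]
    params: Params

    @property
    def auc(self) -> float:
        """Global pooled AUC."""
        return self.roc.auc

    @property
    def mean_disease_auc(self) -> float:
        """Unweighted mean of per-disease AUCs."""
        return float(np.mean(list(self.per_disease_auc.values())))


def confusion_rates(tp, fp, tn, fn) -> tuple[float, float]:
    """(TPR, FPR) with the 0/0 -> 0 convention."""
    for v in (tp, fp, tn, fn):
        if np.any(np.asarray(v) < 0):
            raise ValueError("confusion counts must be nonnegative")
    tp, fp, tn, fn = (np.asarray(v, dtype=float) for v in (tp, fp, tn, fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        fpr = np.where(tn + fp > 0, fp / (tn + fp), 0.0)
    if tpr.ndim == 0:
        return float(tpr), float(fpr)
    return tpr, fpr


def pooled_roc(fold_records: list[tuple[int, int]]) -> ROCResult:
    """ROC from (held-out rank, candidate count) fold records.

    Per fold at cutoff c: the top min(c, n) candidates are predicted
    positive; the single positive is recovered iff its rank <= c.
    """
    if not fold_records:
        raise ValueError("no fold records")
    ranks = np.array([r for r, _ in fold_records])
    sizes = np.array([n for _, n in fold_records])
    if np.any(ranks < 1) or np.any(ranks > sizes):
        raise ValueError("held-out rank outside [1, candidate count]")
    cutoffs = np.arange(0, sizes.max() + 1)  # every list position, plus 0
    n_folds = len(ranks)
    tp = (ranks[None, :] <= cutoffs[:, None]).sum(axis=1)
    called = np.minimum(cutoffs[:, None], sizes[None, :]).sum(axis=1)
    fp = called - tp
    fn = n_folds - tp
    tn = sizes.sum() - n_folds - fp
    tpr, fpr = confusion_rates(tp, fp, tn, fn)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(cutoffs, tpr, fpr, auc, tp, fp, tn, fn)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(positive outranks negative), ties counted half (rank statistic).

    Degenerate label sets (no positives or no negatives) return 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    r = rankdata(scores)  # average ranks handle ties
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _held_out_rank(scores: np.ndarray, candidates: np.ndarray, i: int) -> int:
    """1-based rank of miRNA ``i`` among ``candidates`` by descending score,
    ties broken by input id order."""
    si = scores[i]
    better = 0
    for m in candidates:
        if m == i:
            continue
        if scores[m] > si or (scores[m] == si and m < i):
            better += 1
    return better + 1


def _fold_components(
    AS: AssociationMatrix,
    scorer: Scorer,
):
    """Yield per-fold data: (i, j, candidates, s1, s2, s_disease columns)."""
    values = AS.values
    zero_rows = {
        j: np.where(values[:, j] == 0)[0] for j in range(values.shape[1])
    }
    for i, j in zip(*np.nonzero(values)):
        as_col = values[:, j].astype(float)
        as_col[i] = 0.0
        s1, s2, s_mirna = scorer.mirna_space_column(as_col)
        # column j never weights itself in disease space, so the original
        # matrix is exact here even with (i, j) held out
        s_disease = scorer.disease_space_column(j, values)
        candidates = np.sort(np.append(zero_rows[j], i))
        yield int(i), int(j), candidates, s1, s2, s_mirna, s_disease


def loocv(
    AS: AssociationMatrix,
    mirna_sim: np.ndarray,
    SD: np.ndarray,
    CLU: BinaryRelationMatrix | None = None,
    params: Params | None = None,
    cluster_fallback: bool = False,
) -> CVReport:
    """Leave-one-out cross-validation over all known associations."""
    params = params or Params()
    if AS.values.sum() == 0:
        raise ValueError("association matrix has no known associations")
    scorer = Scorer(AS, mirna_sim, SD, CLU, params, cluster_fallback)
    b = params.beta
    folds: list[FoldRecord] = []
    by_disease: dict[str, list[tuple[int, int]]] = {}
    for i, j, candidates, _, _, s_mirna, s_disease in _fold_components(AS, scorer):
        fc = b * s_mirna + (1.0 - b) * s_disease
        rank = _held_out_rank(fc, candidates, i)
        rec = FoldRecord(
            AS.mirna_ids[i], AS.disease_ids[j], rank, len(candidates)
        )
        folds.append(rec)
        by_disease.setdefault(rec.disease, []).append((rank, rec.n_candidates))
    roc = pooled_roc([(f.rank, f.n_candidates) for f in folds])
    per_disease = {d: pooled_roc(rs).auc for d, rs in by_disease.items()}
    return CVReport(roc, per_disease, folds, params)


def isolated_disease_eval(
    disease: str,
    AS: AssociationMatrix,
    mirna_sim: np.ndarray,
    SD: np.ndarray,
    CLU: BinaryRelationMatrix | None = None,
    params: Params | None = None,
) -> tuple[list[str], float]:
    """Cold-start evaluation for one disease.

    All of the disease's known associations are removed; every miRNA is
    scored and ranked, and the AUC is the probability (tie-corrected) that
    a truly associated miRNA outranks a non-associated one.
    """
    params = params or Params()
    if disease not in AS.disease_index:
        raise KeyError(f"unknown disease {disease!r}")
    j = AS.disease_index[disease]
    labels = AS.values[:, j].copy()
    if labels.sum() == 0:
        raise ValueError(f"disease {disease!r} has no known associations to score")
    values = AS.values.astype(float).copy()
    values[:, j] = 0.0
    scorer = Scorer(AS, mirna_sim, SD, CLU, params)
    fc, _ = scorer.score_column(j, values)
    order = sorted(range(len(fc)), key=lambda m: (-fc[m], m))
    ranked = [AS.mirna_ids[m] for m in order]
    return ranked, mann_whitney_auc(fc, labels)


def isolated_mirna_eval(
    mirna: str,
    AS: AssociationMatrix,
    mirna_sim: np.ndarray,
    SD: np.ndarray,
    CLU: BinaryRelationMatrix | None = None,
    params: Params | None = None,
) -> tuple[list[str], float]:
    """Cold-start evaluation for one miRNA (mirror of the disease case)."""
    params = params or Params()
    if mirna not in AS.mirna_index:
        raise KeyError(f"unknown miRNA {mirna!r}")
    i = AS.mirna_index[mirna]
    labels = AS.values[i, :].copy()
    if labels.sum() == 0:
        raise ValueError(f"miRNA {mirna!r} has no known associations to score")
    values = AS.values.astype(float).copy()
    values[i, :] = 0.0
    scorer = Scorer(AS, mirna_sim, SD, CLU, params)
    comp = scorer.score_matrix(values)
    row = comp.fc[i]
    order = sorted(range(len(row)), key=lambda d: (-row[d], d))
    ranked = [AS.disease_ids[d] for d in order]
    return ranked, mann_whitney_auc(row, labels)


def parameter_grid(
    AS: AssociationMatrix,
    mirna_sim: np.ndarray,
    SD: np.ndarray,
    CLU: BinaryRelationMatrix | None,
    alphas: list[float],
    betas: list[float],
    params: Params | None = None,
) -> pd.DataFrame:
    """Grid of global LOOCV AUC over (alpha, beta) values.

    The per-fold score components are computed once and re-blended per
    grid point.  Returns a frame with columns (alpha, beta, auc) and the
    argmax row flagged in column ``best``.
    """
    if not alphas or not betas:
        raise ValueError("empty parameter grid")
    base = params or Params()
    probe = Params(
        alpha=base.alpha, beta=base.beta, gamma=base.gamma,
        k1=base.k1, k2=base.k2, delta=base.delta,
        cluster_threshold_bp=base.cluster_threshold_bp,
    )
    scorer = Scorer(AS, mirna_sim, SD, CLU, probe)
    cached = [
        (i, j, cand, s1, s2, sdis)
        for i, j, cand, s1, s2, _, sdis in _fold_components(AS, scorer)
    ]
    rows = []
    for a in alphas:
        for b in betas:
            Params(alpha=a, beta=b)  # validate ranges
            records = []
            for i, j, cand, s1, s2, sdis in cached:
                fc = b * (a * s1 + (1 - a) * s2) + (1 - b) * sdis
                records.append((_held_out_rank(fc, cand, i), len(cand)))
            rows.append((a, b, pooled_roc(records).auc))
    frame = pd.DataFrame(rows, columns=["alpha", "beta", "auc"])
    frame["best"] = False
    frame.loc[frame["auc"].idxmax(), "best"] = True
    return frame


def permute_associations(
    AS: AssociationMatrix, rng: np.random.Generator
) -> AssociationMatrix:
    """Negative-control matrix: shuffle miRNA assignments within each
    disease column independently.

    Disease degrees are preserved while the coupling of associations to
    the miRNA and disease similarity networks is destroyed, so LOOCV on
    the result should sit at chance level.
    """
    values = AS.values.copy()
    for j in range(values.shape[1]):
        rng.shuffle(values[:, j])
    return AssociationMatrix(values, list(AS.mirna_ids), list(AS.disease_ids))
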