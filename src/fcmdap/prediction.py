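"""k-nearest-neighbor recommendation scores in miRNA and disease space.

Scores for a (miRNA i, disease j) pair:

* s1 — similarity-weighted fraction of i's top-k1 most similar miRNAs
  that are known-associated with j (weights from the family-boosted
  miRNA similarity network);
* s2 — the same weighted fraction over i's genomic cluster members;
* S_miRNA = alpha*s1 + (1-alpha)*s2 — miRNA-space blend;
* S_disease — weighted fraction of j's top-k2 most similar diseases that
  are known-associated with i (weights from integrated disease
  similarity);
* FC = beta*S_miRNA + (1-beta)*S_disease — the final prediction score.

All weighted fractions use the full weight sum of the selected neighbors
as denominator, so every component lies in [0, 1]; a zero denominator
(no neighbors, no cluster, no positive similarity) yields score 0,
encoding "no evidence".  Neighbor selection excludes the entity itself
and breaks ties by input id order, making runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AssociationMatrix, BinaryRelationMatrix
from .similarity import Params

__all__ = [
    "ScoreMatrix",
    "ScoreComponents",
    "Scorer",
    "neighbor_score_s1",
    "cluster_score_s2",
    "mirna_space_score",
    "disease_space_score",
    "final_scores",
]


@dataclass
class ScoreMatrix:
    """A miRNA x disease score matrix for one score component."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]
    component: str  # s1 | s2 | S_miRNA | S_disease | FC_md
    params: Params = field(default_factory=Params)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match id lists")


@dataclass
class ScoreComponents:
    s1: np.ndarray
    s2: np.ndarray
    s_mirna: np.ndarray
    s_disease: np.ndarray
    fc: np.ndarray


def _top_neighbors(row: np.ndarray, self_idx: int, k: int):
    """Indices/weights of up to k positive-similarity neighbors, descending,
    ties broken by index order (stable)."""
    idx = np.arange(row.size)
    mask = (idx != self_idx) & (row > 0)
    cand = idx[mask]
    order = cand[np.argsort(-row[cand], kind="stable")][:k]
    return order, row[order]


class Scorer:
    """Precomputed normalized-weight operators for fast column scoring.

    The per-column contract: scoring only disease j's column equals the
    corresponding column of the full-matrix computation exactly, which is
    what makes leave-one-out evaluation cheap — all weights depend only on
    the similarity networks, never on the association matrix.
    """

    def __init__(
        self,
        AS: AssociationMatrix,
        mirna_sim: np.ndarray,
        SD: np.ndarray,
        CLU: BinaryRelationMatrix | None,
        params: Params | None = None,
        cluster_fallback: bool = False,
    ):
        self.AS = AS
        self.params = params or Params()
        self.cluster_fallback = cluster_fallback
        nm, nd = AS.values.shape
        mirna_sim = np.asarray(mirna_sim, dtype=float)
        SD = np.asarray(SD, dtype=float)
        if mirna_sim.shape != (nm, nm):
            raise ValueError("miRNA similarity shape mismatch")
        if SD.shape != (nd, nd):
            raise ValueError("disease similarity shape mismatch")

        # s1 operator: row i holds the normalized weights of i's top-k1 neighbors
        self.W1 = np.zeros((nm, nm))
        for i in range(nm):
            nbrs, w = _top_neighbors(mirna_sim[i], i, self.params.k1)
            total = w.sum()
            if total > 0:
                self.W1[i, nbrs] = w / total

        # s2 operator over genomic cluster members
        self.W2 = np.zeros((nm, nm))
        self.has_cluster = np.zeros(nm, dtype=bool)
        if CLU is not None:
            w2 = mirna_sim * CLU.values
            totals = w2.sum(axis=1)
            pos = totals > 0
            self.W2[pos] = w2[pos] / totals[pos, None]
            self.has_cluster = pos

        # disease-space operator: column j holds normalized weights of j's
        # top-k2 neighbor diseases
        self.V = np.zeros((nd, nd))
        for j in range(nd):
            nbrs, w = _top_neighbors(SD[:, j], j, self.params.k2)
            total = w.sum()
            if total > 0:
                self.V[nbrs, j] = w / total

    # -- column-restricted scoring -------------------------------------

    def mirna_space_column(self, as_col: np.ndarray) -> tuple[np.ndarray, ...]:
        """(s1, s2, S_miRNA) for all miRNAs against one AS column."""
        a = self.params.alpha
        s1 = self.W1 @ as_col
        s2 = self.W2 @ as_col
        s_mirna = a * s1 + (1.0 - a) * s2
        if self.cluster_fallback:
            # optional renormalisation: no cluster -> fall back to s1 alone
            s_mirna = np.where(self.has_cluster, s_mirna, s1)
        return s1, s2, s_mirna

    def disease_space_column(self, j: int, as_values: np.ndarray) -> np.ndarray:
        """S_disease for all miRNAs against disease column ``j``.

        Depends on AS rows over j's neighbor diseases only — never on
        column j itself (j is excluded from its own neighbor list).
        """
        return as_values @ self.V[:, j]

    def score_column(
        self, j: int, as_values: np.ndarray | None = None
    ) -> tuple[np.ndarray, ScoreComponents]:
        if as_values is None:
            as_values = self.AS.values
        as_values = np.asarray(as_values, dtype=float)
        s1, s2, s_mirna = self.mirna_space_column(as_values[:, j])
        s_disease = self.disease_space_column(j, as_values)
        b = self.params.beta
        fc = b * s_mirna + (1.0 - b) * s_disease
        return fc, ScoreComponents(s1, s2, s_mirna, s_disease, fc)

    # -- full matrix ----------------------------------------------------

    def score_matrix(
        self, as_values: np.ndarray | None = None
    ) -> ScoreComponents:
        if as_values is None:
            as_values = self.AS.values
        as_values = np.asarray(as_values, dtype=float)
        a, b = self.params.alpha, self.params.beta
        s1 = self.W1 @ as_values
        s2 = self.W2 @ as_values
        s_mirna = a * s1 + (1.0 - a) * s2
        if self.cluster_fallback:
            s_mirna = np.where(self.has_cluster[:, None], s_mirna, s1)
        s_disease = as_values @ self.V
        fc = b * s_mirna + (1.0 - b) * s_disease
        return ScoreComponents(s1, s2, s_mirna, s_disease, fc)


# -- scalar reference operations (id-level surface) ---------------------


def _indices(AS: AssociationMatrix, i: str, j: str) -> tuple[int, int]:
    if i not in AS.mirna_index:
        raise KeyError(f"unknown miRNA {i!r}")
    if j not in AS.disease_index:
        raise KeyError(f"unknown disease {j!r}")
    return AS.mirna_index[i], AS.disease_index[j]


def neighbor_score_s1(
    i: str,
    j: str,
    mirna_sim: np.ndarray,
    AS: AssociationMatrix,
    k1: int,
) -> float:
    """Weighted fraction of i's top-k1 similar miRNAs associated with j."""
    if k1 < 1:
        raise ValueError("k1 must be >= 1")
    ii, jj = _indices(AS, i, j)
    nbrs, w = _top_neighbors(np.asarray(mirna_sim, dtype=float)[ii], ii, k1)
    total = w.sum()
    if total == 0:
        return 0.0
    return float(w @ AS.values[nbrs, jj] / total)


def cluster_score_s2(
    i: str,
    j: str,
    mirna_sim: np.ndarray,
    CLU: BinaryRelationMatrix,
    AS: AssociationMatrix,
) -> float:
    """Weighted fraction of i's genomic cluster members associated with j."""
    ii, jj = _indices(AS, i, j)
    w = np.asarray(mirna_sim, dtype=float)[ii] * CLU.values[ii]
    total = w.sum()
    if total == 0:
        return 0.0
    return float(w @ AS.values[:, jj] / total)


def mirna_space_score(s1: float, s2: float, alpha: float = 0.5) -> float:
    """S_miRNA = alpha*s1 + (1-alpha)*s2, applied unconditionally."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha * s1 + (1.0 - alpha) * s2


def disease_space_score(
    i: str,
    j: str,
    SD: np.ndarray,
    AS: AssociationMatrix,
    k2: int,
) -> float:
    """Weighted fraction of j's top-k2 similar diseases associated with i."""
    if k2 < 1:
        raise ValueError("k2 must be >= 1")
    ii, jj = _indices(AS, i, j)
    nbrs, w = _top_neighbors(np.asarray(SD, dtype=float)[:, jj], jj, k2)
    total = w.sum()
    if total == 0:
        return 0.0
    return float(AS.values[ii, nbrs] @ w / total)


def final_scores(
    AS: AssociationMatrix,
    mirna_sim: np.ndarray,
    SD: np.ndarray,
    CLU: BinaryRelationMatrix | None,
    params: Params | None = None,
    cluster_fallback: bool = False,
) -> ScoreMatrix:
    """Full FC score matrix over every (miRNA, disease) pair.

    Isolated diseases (all-zero AS column) come out as (1-beta)*S_disease
    and isolated miRNAs (all-zero row) as beta*S_miRNA with no special
    casing — the zero column/row drives the other space's score to 0.
    """
    params = params or Params()
    scorer = Scorer(AS, mirna_sim, SD, CLU, params, cluster_fallback)
    comp = scorer.score_matrix()
    return ScoreMatrix(comp.fc, AS.mirna_ids, AS.disease_ids, "FC_md", params)
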