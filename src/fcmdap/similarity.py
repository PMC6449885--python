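"""Entropy / mutual-information similarity kernel and network assembly.

The same kernel serves both miRNA functional similarity (over shared
target mRNAs) and disease functional similarity (over shared interaction
genes).  Each entity's profile is its target set; a target t carries the
global weight p(t) = n(t)/N, where n(t) counts the sources interacting
with t and N is the total interaction count.  The profile "entropy"

    H(S) = -sum_{t in S} p(t) * log2 p(t)

is a sum of per-target information weights over the profile (the p(t) do
not sum to 1 over a profile; the formula is applied literally, not
renormalised).  Similarity is the normalised shared information

    SM(A, B) = 2 * H(T_A & T_B) / (H(T_A) + H(T_B))

which lies in [0, 1] because the intersection's (nonnegative) term sum is
a subset of each profile's.  Log base cancels between numerator and
denominator; base 2 is fixed so entropy values themselves are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryRelationMatrix, InteractionTable

__all__ = [
    "Params",
    "profile_entropy",
    "intersection_entropy",
    "mi_similarity",
    "family_boost",
    "integrate_disease_similarity",
]


@dataclass
class Params:
    """Model hyperparameters.

    alpha blends the neighbor score s1 with the cluster score s2 in miRNA
    space; beta blends the miRNA-space and disease-space scores; gamma
    blends disease functional and semantic similarity; k1 / k2 are the
    neighbor counts in miRNA / disease space; delta is the semantic decay
    per DAG edge; cluster_threshold_bp is the genomic co-cluster cutoff.
    """

    alpha: float = 0.5
    beta: float = 0.8
    gamma: float = 0.5
    k1: int = 50
    k2: int = 30
    delta: float = 0.5
    cluster_threshold_bp: int = 20_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("k1 and k2 must be positive integers")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.cluster_threshold_bp <= 0:
            raise ValueError("cluster_threshold_bp must be positive")


def _entropy_of_targets(targets, table: InteractionTable) -> float:
    if table.N == 0:
        raise ValueError("empty interaction table")
    h = 0.0
    for t in targets:
        p = table.target_counts[t] / table.N
        if p < 1.0:
            h -= p * np.log2(p)
        # p == 1 contributes exactly 0
    return h


def profile_entropy(entity: str, table: InteractionTable) -> float:
    """H of the entity's target profile, in bits; 0 for an empty profile."""
    return _entropy_of_targets(table.targets_of(entity), table)


def intersection_entropy(a: str, b: str, table: InteractionTable) -> float:
    """H of the shared targets of ``a`` and ``b`` under the same global p(t)."""
    return _entropy_of_targets(
        table.targets_of(a) & table.targets_of(b), table
    )


def mi_similarity(table: InteractionTable, ids: list[str]) -> np.ndarray:
    """Pairwise normalised-MI similarity matrix over ``ids``.

    Entities absent from the table have empty profiles: their rows are
    zero, including the diagonal (no evidence means no self-similarity
    for recommendation purposes).  In-table entities get diagonal 1.
    """
    if table.N == 0:
        raise ValueError("empty interaction table")
    n = len(ids)
    H = np.array([profile_entropy(e, table) for e in ids])
    nonempty = np.array([len(table.targets_of(e)) > 0 for e in ids])
    SM = np.zeros((n, n), dtype=float)
    for i in range(n):
        if not nonempty[i]:
            continue
        SM[i, i] = 1.0
        for j in range(i + 1, n):
            if not nonempty[j]:
                continue
            denom = H[i] + H[j]
            if denom == 0.0:
                continue
            h_int = intersection_entropy(ids[i], ids[j], table)
            val = 2.0 * h_int / denom
            SM[i, j] = SM[j, i] = val
    return SM


def family_boost(SM: np.ndarray, FAM: BinaryRelationMatrix) -> np.ndarray:
    """Reconstructed miRNA similarity: SM * (1 + FAM), elementwise.

    Same-family pairs have their similarity doubled; the result may exceed
    1 (range [0, 2]) and is deliberately left uncapped — downstream scores
    normalise by the same weights, so they stay in [0, 1].
    """
    SM = np.asarray(SM, dtype=float)
    if SM.shape != FAM.values.shape:
        raise ValueError("SM and FAM shapes do not match")
    return SM * (1.0 + FAM.values)


def integrate_disease_similarity(
    SDF: np.ndarray, DD: np.ndarray, gamma: float = 0.5
) -> np.ndarray:
    """Convex combination SD = gamma*SDF + (1-gamma)*DD.

    Diseases missing from the gene table contribute SDF = 0 and diseases
    missing from the DAG contribute DD = 0; the formula is applied as-is.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    SDF = np.asarray(SDF, dtype=float)
    DD = np.asarray(DD, dtype=float)
    if SDF.shape != DD.shape:
        raise ValueError("SDF and DD shapes do not match")
    return gamma * SDF + (1.0 - gamma) * DD
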