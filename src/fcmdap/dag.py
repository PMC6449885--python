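"""Disease semantic similarity on the MeSH Category-C DAG.

Each disease contributes to its own semantics with weight 1; an ancestor
t contributes D_A(t) = delta * max over t's children on paths toward A,
the standard decayed-contribution (Wang-style) semantic measure.  The
semantic value DV(A) is the sum of contributions over A's ancestor set
(A included).  Similarity of two diseases compares the contributions of
their shared ancestors:

    DD(A, B) = [sum_{t in T_A & T_B} D_A(t) + sum D_B(t)]
               / (2 * min(DV(A), DV(B)))

FCMDAP defines the denominator with the min; since it can
push the ratio above 1 (unlike the conventional DV(A)+DV(B) form, which
is available via ``denominator="sum"``), raw values above 1 are clamped
with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["DiseaseDAG", "ancestor_contributions", "semantic_similarity"]


class DiseaseDAG:
    """Disease nodes with parent links derived from MeSH tree numbers."""

    def __init__(self, parents: dict[str, set[str]]):
        self.parents = {n: set(p) for n, p in parents.items()}
        for n, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise ValueError(f"node {n!r} has unknown parents {unknown}")
        self._check_acyclic()

    @property
    def nodes(self) -> list[str]:
        return list(self.parents)

    def __contains__(self, node: str) -> bool:
        return node in self.parents

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            state[n] = 1
            for p in self.parents[n]:
                s = state.get(p)
                if s == 1:
                    raise ValueError(f"cycle in disease DAG at {n!r}")
                if s is None:
                    visit(p)
            state[n] = 2

        for n in self.parents:
            if n not in state:
                visit(n)

    def ancestors(self, node: str) -> set[str]:
        """Ancestor set of ``node``, including the node itself."""
        if node not in self.parents:
            raise KeyError(f"unknown disease {node!r}")
        out = {node}
        stack = [node]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


def ancestor_contributions(
    node: str, dag: DiseaseDAG, delta: float = 0.5
) -> tuple[dict[str, float], float]:
    """Decayed semantic contributions of ``node``'s ancestors and their sum DV.

    D(node)=1; for an ancestor t, D(t) = delta * max over children of t on
    paths toward ``node`` of D(child) — i.e. delta**(shortest path length).
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if node not in dag:
        raise KeyError(f"unknown disease {node!r}")
    contrib: dict[str, float] = {node: 1.0}
    # max-decay relaxation; terminates because delta < 1 and the DAG is acyclic
    stack = [node]
    while stack:
        n = stack.pop()
        cand = delta * contrib[n]
        for p in dag.parents[n]:
            if cand > contrib.get(p, 0.0):
                contrib[p] = cand
                stack.append(p)
    return contrib, float(sum(contrib.values()))


def semantic_similarity(
    dag: DiseaseDAG,
    ids: list[str],
    delta: float = 0.5,
    denominator: str = "min",
) -> np.ndarray:
    """Pairwise semantic similarity matrix DD over ``ids``.

    Diseases absent from the DAG get all-zero rows (and a zero diagonal);
    in-DAG diseases have DD(A, A) = 1.  ``denominator`` selects the printed
    ``"min"`` form (default) or the conventional ``"sum"`` form
    2*sum(shared)/(DV(A)+DV(B)).
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if denominator not in ("min", "sum"):
        raise ValueError("denominator must be 'min' or 'sum'")
    n = len(ids)
    contrib: dict[str, dict[str, float]] = {}
    dv: dict[str, float] = {}
    for d in ids:
        if d in dag:
            c, v = ancestor_contributions(d, dag, delta)
            contrib[d], dv[d] = c, v
    DD = np.zeros((n, n), dtype=float)
    clamped = 0
    for i, a in enumerate(ids):
        if a not in contrib:
            continue
        DD[i, i] = 1.0
        for j in range(i + 1, n):
            b = ids[j]
            if b not in contrib:
                continue
            ca, cb = contrib[a], contrib[b]
            shared = ca.keys() & cb.keys()
            if not shared:
                continue
            num = sum(ca[t] for t in shared) + sum(cb[t] for t in shared)
            if denominator == "min":
                den = 2.0 * min(dv[a], dv[b])
            else:
                den = dv[a] + dv[b]
            val = num / den
            if val > 1.0:
                clamped += 1
                val = 1.0
            DD[i, j] = DD[j, i] = val
    if clamped:
        warnings.warn(
            f"clamped {clamped} semantic similarity value(s) above 1 "
            "(min-denominator artefact)"
        )
    return DD
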