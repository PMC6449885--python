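"""Model/results facade tying the pipeline together.

``FCMDAP`` is built from the input tables (or files, or a synthetic
bundle); ``fit()`` assembles the miRNA and disease similarity networks
and the full score matrix, returning a ``FCMDAPResults`` with the score
components, ranking, cross-validation and plotting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, io, prediction
from .dag import DiseaseDAG, semantic_similarity
from .io import (
    AssociationMatrix,
    BinaryRelationMatrix,
    CoordinateTable,
    InteractionTable,
)
from .similarity import (
    Params,
    family_boost,
    integrate_disease_similarity,
    mi_similarity,
)
from .synthetic import DatasetBundle

__all__ = ["FCMDAP", "FCMDAPResults"]


def _resolve_ids(ids: list[str], available) -> list[str]:
    """Map ids onto ``available`` keys, case-insensitively after trimming.

    Source databases capitalise disease names inconsistently; an id with
    no (normalised) match is returned unchanged and will simply have an
    empty profile downstream.
    """
    lookup: dict[str, str] = {}
    for key in available:
        lookup.setdefault(key.strip().lower(), key)
    return [lookup.get(i.strip().lower(), i) for i in ids]


class FCMDAP:
    """miRNA-disease association predictor.

    Parameters
    ----------
    associations : AssociationMatrix
        Known binary miRNA-disease associations.
    mirna_targets : InteractionTable
        Experimentally verified miRNA-mRNA interactions.
    disease_genes : InteractionTable, optional
        Disease-gene interactions for disease functional similarity.
    family : BinaryRelationMatrix, optional
        miRNA family co-membership (doubles same-family similarity).
    coordinates : CoordinateTable, optional
        miRNA genomic locations; pairs closer than the cluster threshold
        form genomic clusters driving the s2 score.
    mesh : DiseaseDAG, optional
        Disease DAG from MeSH tree numbers for semantic similarity.
    params : Params, optional
        Hyperparameters (alpha, beta, gamma, k1, k2, delta, cluster
        threshold).
    """

    def __init__(
        self,
        associations: AssociationMatrix,
        mirna_targets: InteractionTable,
        disease_genes: InteractionTable | None = None,
        family: BinaryRelationMatrix | None = None,
        coordinates: CoordinateTable | None = None,
        mesh: DiseaseDAG | None = None,
        params: Params | None = None,
        cluster_fallback: bool = False,
        dd_denominator: str = "min",
    ):
        self.associations = associations
        self.mirna_targets = mirna_targets
        self.disease_genes = disease_genes
        self.family = family
        self.coordinates = coordinates
        self.mesh = mesh
        self.params = params or Params()
        self.cluster_fallback = cluster_fallback
        self.dd_denominator = dd_denominator

    @classmethod
    def from_files(
        cls,
        associations,
        mirna_targets,
        disease_genes=None,
        family=None,
        gff=None,
        mesh=None,
        params: Params | None = None,
        **kwargs,
    ) -> "FCMDAP":
        """Build the model from the TSV/GFF3 input files."""
        AS = io.read_associations(associations)
        return cls(
            AS,
            io.read_interactions(mirna_targets),
            io.read_interactions(disease_genes) if disease_genes else None,
            io.read_family(family, AS.mirna_ids) if family else None,
            io.read_coordinates(gff) if gff else None,
            io.read_mesh_tree(mesh) if mesh else None,
            params=params,
            **kwargs,
        )

    @classmethod
    def from_bundle(
        cls, bundle: DatasetBundle, params: Params | None = None, **kwargs
    ) -> "FCMDAP":
        """Build the model from a synthetic dataset bundle."""
        AS = bundle.associations
        fam = _family_from_pairs(bundle.family, AS.mirna_ids) if bundle.family else None
        dag = _dag_from_rows(bundle.mesh) if bundle.mesh else None
        return cls(
            AS,
            bundle.mirna_targets,
            bundle.disease_genes,
            fam,
            bundle.coordinates,
            dag,
            params=params,
            **kwargs,
        )

    def fit(self) -> "FCMDAPResults":
        """Assemble similarity networks and score every pair."""
        AS = self.associations
        p = self.params
        SM = mi_similarity(self.mirna_targets, AS.mirna_ids)
        if self.family is not None:
            mirna_sim = family_boost(SM, self.family)
        else:
            mirna_sim = SM
        nd = len(AS.disease_ids)
        if self.disease_genes is not None:
            gene_ids = _resolve_ids(
                AS.disease_ids, self.disease_genes.sources
            )
            SDF = mi_similarity(self.disease_genes, gene_ids)
        else:
            SDF = np.zeros((nd, nd))
        if self.mesh is not None:
            dag_ids = _resolve_ids(AS.disease_ids, self.mesh.nodes)
            DD = semantic_similarity(
                self.mesh, dag_ids, p.delta, self.dd_denominator
            )
        else:
            DD = np.zeros((nd, nd))
        SD = integrate_disease_similarity(SDF, DD, p.gamma)
        CLU = None
        if self.coordinates is not None:
            CLU = io.build_cluster_matrix(
                self.coordinates, AS.mirna_ids, p.cluster_threshold_bp
            )
        scorer = prediction.Scorer(
            AS, mirna_sim, SD, CLU, p, self.cluster_fallback
        )
        components = scorer.score_matrix()
        return FCMDAPResults(
            self, scorer, components, SM, mirna_sim, SDF, DD, SD, CLU
        )


def _family_from_pairs(
    pairs: list[tuple[str, str]], mirna_ids: list[str]
) -> BinaryRelationMatrix:
    index = {m: i for i, m in enumerate(mirna_ids)}
    by_family: dict[str, list[int]] = {}
    for m, fam in pairs:
        if m in index:
            by_family.setdefault(fam, []).append(index[m])
    n = len(mirna_ids)
    values = np.zeros((n, n), dtype=np.int8)
    for members in by_family.values():
        for a in members:
            for b in members:
                if a != b:
                    values[a, b] = 1
    return BinaryRelationMatrix(values, list(mirna_ids), role="family")


def _dag_from_rows(rows: list[tuple[str, str]]) -> DiseaseDAG:
    owner: dict[str, str] = {}
    tree_numbers: dict[str, list[str]] = {}
    for d, tn in rows:
        owner[tn] = d
        tree_numbers.setdefault(d, []).append(tn)
    parents: dict[str, set[str]] = {d: set() for d in tree_numbers}
    for d, tns in tree_numbers.items():
        for tn in tns:
            if "." in tn:
                parent = owner.get(tn.rsplit(".", 1)[0])
                if parent is not None and parent != d:
                    parents[d].add(parent)
    return DiseaseDAG(parents)


class FCMDAPResults:
    """Fitted scores plus evaluation and export helpers."""

    def __init__(
        self, model, scorer, components, SM, mirna_sim, SDF, DD, SD, CLU
    ):
        self.model = model
        self.scorer = scorer
        self.components = components
        self.mirna_functional_similarity = SM
        self.mirna_similarity = mirna_sim
        self.disease_functional_similarity = SDF
        self.disease_semantic_similarity = DD
        self.disease_similarity = SD
        self.cluster_matrix = CLU

    # -- accessors ------------------------------------------------------

    @property
    def scores(self) -> pd.DataFrame:
        """Final prediction scores, miRNAs x diseases."""
        AS = self.model.associations
        return pd.DataFrame(
            self.components.fc, index=AS.mirna_ids, columns=AS.disease_ids
        )

    def component(self, name: str) -> pd.DataFrame:
        """One score component: s1, s2, S_miRNA, S_disease or FC_md."""
        key = {
            "s1": "s1", "s2": "s2", "S_miRNA": "s_mirna",
            "S_disease": "s_disease", "FC_md": "fc",
        }.get(name)
        if key is None:
            raise KeyError(f"unknown component {name!r}")
        AS = self.model.associations
        return pd.DataFrame(
            getattr(self.components, key),
            index=AS.mirna_ids,
            columns=AS.disease_ids,
        )

    def rank_mirnas(self, disease: str, top: int = 50) -> pd.DataFrame:
        """Top candidate miRNAs (no verified association) for a disease."""
        AS = self.model.associations
        if disease not in AS.disease_index:
            import difflib

            near = difflib.get_close_matches(disease, AS.disease_ids, n=5, cutoff=0.4)
            hint = f"; near matches: {', '.join(near)}" if near else ""
            raise KeyError(f"unknown disease {disease!r}{hint}")
        j = AS.disease_index[disease]
        col = self.components.fc[:, j]
        candidates = [i for i in range(len(AS.mirna_ids)) if AS.values[i, j] == 0]
        order = sorted(candidates, key=lambda i: (-col[i], i))[:top]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "miRNA": [AS.mirna_ids[i] for i in order],
                "score": [float(col[i]) for i in order],
            }
        )

    # -- evaluation -----------------------------------------------------

    def loocv(self) -> evaluation.CVReport:
        """Leave-one-out cross-validation over all known associations."""
        m = self.model
        return evaluation.loocv(
            m.associations, self.mirna_similarity, self.disease_similarity,
            self.cluster_matrix, m.params, m.cluster_fallback,
        )

    def isolated_disease(self, disease: str) -> tuple[list[str], float]:
        m = self.model
        return evaluation.isolated_disease_eval(
            disease, m.associations, self.mirna_similarity,
            self.disease_similarity, self.cluster_matrix, m.params,
        )

    def isolated_mirna(self, mirna: str) -> tuple[list[str], float]:
        m = self.model
        return evaluation.isolated_mirna_eval(
            mirna, m.associations, self.mirna_similarity,
            self.disease_similarity, self.cluster_matrix, m.params,
        )

    def parameter_grid(
        self, alphas: list[float], betas: list[float]
    ) -> pd.DataFrame:
        m = self.model
        return evaluation.parameter_grid(
            m.associations, self.mirna_similarity, self.disease_similarity,
            self.cluster_matrix, alphas, betas, m.params,
        )

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the dataset, parameters and score ranges."""
        m = self.model
        stats = io.dataset_stats(m.associations)
        p = m.params
        fc = self.components.fc
        lines = [
            "FCMDAP prediction results",
            "=" * 60,
            f"miRNAs: {stats.n_mirnas}    diseases: {stats.n_diseases}    "
            f"known associations: {stats.n_associations}",
            f"avg degree  miRNA: {stats.avg_mirna_degree:.2f}   "
            f"disease: {stats.avg_disease_degree:.2f}",
            f"max degree  miRNA: {stats.max_mirna_degree}   "
            f"disease: {stats.max_disease_degree}",
            "-" * 60,
            f"alpha={p.alpha}  beta={p.beta}  gamma={p.gamma}  "
            f"k1={p.k1}  k2={p.k2}  delta={p.delta}  "
            f"cluster<{p.cluster_threshold_bp} bp",
            f"family matrix: {'yes' if m.family is not None else 'no'}    "
            f"cluster matrix: {'yes' if self.cluster_matrix is not None else 'no'}    "
            f"disease DAG: {'yes' if m.mesh is not None else 'no'}",
            "-" * 60,
            f"score range: [{fc.min():.4f}, {fc.max():.4f}]   "
            f"mean: {fc.mean():.4f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, roc: evaluation.ROCResult, path=None, ax=None):
        """Plot a pooled ROC curve; writes to ``path`` if given."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.4f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax
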