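"""Input parsing and the core data model.

All pair tables are tab-delimited text with an optional single header
line; genomic coordinates come as miRBase-style GFF3; disease MeSH tree
numbers as a two-column (disease, tree number) table.
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dag import DiseaseDAG

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "AssociationMatrix",
    "BinaryRelationMatrix",
    "CoordinateTable",
    "CoordinateRecord",
    "StatsSummary",
    "read_associations",
    "read_interactions",
    "read_family",
    "read_coordinates",
    "build_cluster_matrix",
    "read_mesh_tree",
    "dataset_stats",
    "write_rankings",
    "xlsx_to_tsv",
]

# header tokens that mark the optional first line of a pair table
_HEADER_TOKENS = {
    "mirna", "mirna_id", "disease", "disease_id", "source", "target",
    "gene", "gene_id", "mrna", "mrna_id", "family", "family_id", "name",
    "tree_number", "tree", "id",
}


def _read_pair_lines(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV into a list of (a, b) string pairs.

    Lines starting with '#' are comments.  A single leading header line is
    recognised by its tokens (e.g. "miRNA<TAB>disease") and dropped.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}: {line!r}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not pairs and lineno <= 2 and (
                a.lstrip("#").lower() in _HEADER_TOKENS
                or b.lower() in _HEADER_TOKENS
            ):
                continue  # header line
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty field")
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path}: no data rows")
    return pairs


@dataclass
class InteractionTable:
    """A bipartite source -> target pair set with global target counts.

    ``N`` is the total number of unique interactions and ``target_counts``
    maps each target to the number of sources it interacts with; these are
    the n(.) and N of the entropy weighting p(t) = n(t)/N.
    """

    pairs: set[tuple[str, str]]
    N: int = field(init=False)
    target_counts: dict[str, int] = field(init=False)
    _targets_by_source: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.N = len(self.pairs)
        counts: dict[str, int] = {}
        by_source: dict[str, set[str]] = {}
        for s, t in self.pairs:
            counts[t] = counts.get(t, 0) + 1
            by_source.setdefault(s, set()).add(t)
        self.target_counts = counts
        self._targets_by_source = {s: frozenset(v) for s, v in by_source.items()}

    def targets_of(self, source: str) -> frozenset[str]:
        """Target set of ``source`` (empty frozenset if unknown)."""
        return self._targets_by_source.get(source, frozenset())

    @property
    def sources(self) -> list[str]:
        return sorted(self._targets_by_source)


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix AS."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        self.mirna_index = {m: i for i, m in enumerate(self.mirna_ids)}
        self.disease_index = {d: j for j, d in enumerate(self.disease_ids)}

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]]
    ) -> "AssociationMatrix":
        """Build from (miRNA, disease) pairs, ids in first-appearance order."""
        mirnas: list[str] = []
        diseases: list[str] = []
        seen_m: set[str] = set()
        seen_d: set[str] = set()
        uniq: set[tuple[str, str]] = set()
        n_dup = 0
        kept: list[tuple[str, str]] = []
        for m, d in pairs:
            if (m, d) in uniq:
                n_dup += 1
                continue
            uniq.add((m, d))
            kept.append((m, d))
            if m not in seen_m:
                seen_m.add(m)
                mirnas.append(m)
            if d not in seen_d:
                seen_d.add(d)
                diseases.append(d)
        if n_dup:
            logger.warning("dropped %d duplicate association pair(s)", n_dup)
            warnings.warn(f"dropped {n_dup} duplicate association pair(s)")
        values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
        mi = {m: i for i, m in enumerate(mirnas)}
        di = {d: j for j, d in enumerate(diseases)}
        for m, d in kept:
            values[mi[m], di[d]] = 1
        return cls(values, mirnas, diseases)

    def to_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]


@dataclass
class BinaryRelationMatrix:
    """Symmetric binary relation (family or cluster co-membership).

    Diagonal forced to zero: the relation is defined for pairs only and a
    nonzero diagonal would inflate self-similarity downstream.
    """

    values: np.ndarray
    ids: list[str]
    role: str  # "family" | "cluster"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relation matrix shape does not match id list")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("relation entries must be 0 or 1")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("relation matrix must be symmetric")
        np.fill_diagonal(self.values, 0)
        if self.role not in ("family", "cluster"):
            raise ValueError(f"unknown relation role {self.role!r}")


@dataclass
class CoordinateRecord:
    chrom: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} for a coordinate record"
            )


class CoordinateTable(dict):
    """Mapping miRNA id -> CoordinateRecord."""


@dataclass
class StatsSummary:
    """Global characteristics of an association network."""

    n_associations: int
    n_mirnas: int
    n_diseases: int
    avg_mirna_degree: float
    avg_disease_degree: float
    max_mirna_degree: int
    min_mirna_degree: int
    max_disease_degree: int
    min_disease_degree: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Characteristic": [
                    "No. of miRNA-disease associations",
                    "No. of miRNAs",
                    "No. of diseases",
                    "Avg. degree of miRNAs",
                    "Avg. degree of diseases",
                    "Max degree of miRNAs",
                    "Min degree of miRNAs",
                    "Max degree of diseases",
                    "Min degree of diseases",
                ],
                "Number": [
                    self.n_associations,
                    self.n_mirnas,
                    self.n_diseases,
                    self.avg_mirna_degree,
                    self.avg_disease_degree,
                    self.max_mirna_degree,
                    self.min_mirna_degree,
                    self.max_disease_degree,
                    self.min_disease_degree,
                ],
            }
        )


def read_associations(path) -> AssociationMatrix:
    """Read a (miRNA, disease) pair table into a binary matrix.

    Duplicated pairs are collapsed with a warning; ids are kept verbatim in
    first-appearance order.
    """
    return AssociationMatrix.from_pairs(_read_pair_lines(path))


def read_interactions(path) -> InteractionTable:
    """Read a (source, target) pair table into an InteractionTable.

    The pair set is deduplicated before N and the target counts are taken.
    """
    return InteractionTable(set(_read_pair_lines(path)))


def read_family(path, mirna_ids: list[str]) -> BinaryRelationMatrix:
    """Read (miRNA, family) assignments into the FAM co-membership matrix.

    FAM(i, j) = 1 iff i != j and both are assigned the same family id.
    miRNAs absent from the file belong to no family.  A miRNA assigned to
    two families is an error.
    """
    assignment: dict[str, str] = {}
    known = set(mirna_ids)
    n_unknown = 0
    for m, fam in _read_pair_lines(path):
        if m in assignment and assignment[m] != fam:
            raise ValueError(
                f"miRNA {m!r} assigned to two families "
                f"({assignment[m]!r}, {fam!r})"
            )
        if m not in known:
            n_unknown += 1
            continue
        assignment[m] = fam
    if n_unknown:
        warnings.warn(
            f"ignored {n_unknown} family assignment(s) for unknown miRNA ids"
        )
    n = len(mirna_ids)
    values = np.zeros((n, n), dtype=np.int8)
    by_family: dict[str, list[int]] = {}
    index = {m: i for i, m in enumerate(mirna_ids)}
    for m, fam in assignment.items():
        by_family.setdefault(fam, []).append(index[m])
    for members in by_family.values():
        for a in members:
            for b in members:
                if a != b:
                    values[a, b] = 1
    return BinaryRelationMatrix(values, list(mirna_ids), role="family")


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        if not chunk or "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_coordinates(path) -> CoordinateTable:
    """Read miRNA genomic coordinates from a miRBase-style GFF3 file.

    The id comes from the Name attribute (ID as fallback).  The first
    record per id wins; later records trigger a warning.
    """
    table = CoordinateTable()
    n_records = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns, "
                    f"got {len(fields)}"
                )
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if "miRNA" not in ftype:  # miRNA or miRNA_primary_transcript
                continue
            n_records += 1
            a = _parse_gff_attributes(attrs)
            name = a.get("Name") or a.get("ID")
            if not name:
                warnings.warn(f"{path}: line {lineno}: record without Name/ID, skipped")
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}: line {lineno}: start > end")
            if name in table:
                warnings.warn(
                    f"{path}: line {lineno}: duplicate record for {name!r}, "
                    "first kept"
                )
                continue
            table[name] = CoordinateRecord(chrom, start_i, end_i, strand)
    if n_records == 0:
        warnings.warn(f"{path}: no miRNA-type records found")
    return table


def build_cluster_matrix(
    coords: CoordinateTable,
    mirna_ids: list[str],
    threshold_bp: int = 20_000,
) -> BinaryRelationMatrix:
    """Build the CLU genomic co-cluster matrix.

    CLU(i, j) = 1 iff i != j, both on the same chromosome, and the gap
    between their genomic intervals (0 when overlapping) is strictly below
    ``threshold_bp``.  Strand is ignored and no transitive closure is
    taken; miRNAs without coordinates get all-zero rows.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")
    n = len(mirna_ids)
    values = np.zeros((n, n), dtype=np.int8)
    present = [(i, coords[m]) for i, m in enumerate(mirna_ids) if m in coords]
    for ai in range(len(present)):
        i, ri = present[ai]
        for bi in range(ai + 1, len(present)):
            j, rj = present[bi]
            if ri.chrom != rj.chrom:
                continue
            gap = max(0, max(ri.start, rj.start) - min(ri.end, rj.end))
            if gap < threshold_bp:
                values[i, j] = values[j, i] = 1
    return BinaryRelationMatrix(values, list(mirna_ids), role="cluster")


def read_mesh_tree(path) -> DiseaseDAG:
    """Read (disease, tree number) rows into a disease DAG.

    A tree number "a.b.c" has parent tree number "a.b"; an edge links a
    disease to the disease owning the parent number.  Diseases whose
    parent number is owned by nobody are roots.  A disease may carry
    several tree numbers; its ancestor set is the union over all of them.
    """
    tree_numbers: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    for disease, tn in _read_pair_lines(path):
        segments = tn.split(".")
        if any(not s for s in segments):
            raise ValueError(f"malformed tree number {tn!r} for {disease!r}")
        if tn in owner and owner[tn] != disease:
            raise ValueError(
                f"tree number {tn!r} assigned to both {owner[tn]!r} and {disease!r}"
            )
        owner[tn] = disease
        tree_numbers.setdefault(disease, [])
        if tn not in tree_numbers[disease]:
            tree_numbers[disease].append(tn)
    parents: dict[str, set[str]] = {d: set() for d in tree_numbers}
    for disease, tns in tree_numbers.items():
        for tn in tns:
            if "." not in tn:
                continue
            parent_tn = tn.rsplit(".", 1)[0]
            parent = owner.get(parent_tn)
            if parent is not None and parent != disease:
                parents[disease].add(parent)
    return DiseaseDAG(parents)


def dataset_stats(AS: AssociationMatrix) -> StatsSummary:
    """Global degree statistics of the association network (averages to 2 dp)."""
    values = AS.values
    if values.size == 0:
        raise ValueError("empty association matrix")
    mirna_deg = values.sum(axis=1)
    disease_deg = values.sum(axis=0)
    n_assoc = int(values.sum())
    return StatsSummary(
        n_associations=n_assoc,
        n_mirnas=len(AS.mirna_ids),
        n_diseases=len(AS.disease_ids),
        avg_mirna_degree=round(n_assoc / len(AS.mirna_ids), 2),
        avg_disease_degree=round(n_assoc / len(AS.disease_ids), 2),
        max_mirna_degree=int(mirna_deg.max()),
        min_mirna_degree=int(mirna_deg.min()),
        max_disease_degree=int(disease_deg.max()),
        min_disease_degree=int(disease_deg.min()),
    )


def write_rankings(
    scores: np.ndarray,
    AS: AssociationMatrix,
    disease: str,
    top_k: int,
    path,
) -> pd.DataFrame:
    """Write the top-k candidate miRNAs for ``disease`` as (rank, miRNA, score).

    Candidates are miRNAs without a verified association to the disease;
    sorted by descending score, ties broken by input miRNA order.  Returns
    the written table.
    """
    if disease not in AS.disease_index:
        near = difflib.get_close_matches(disease, AS.disease_ids, n=5, cutoff=0.4)
        hint = f"; near matches: {', '.join(near)}" if near else ""
        raise KeyError(f"unknown disease {disease!r}{hint}")
    j = AS.disease_index[disease]
    col = np.asarray(scores)[:, j] if np.asarray(scores).ndim == 2 else np.asarray(scores)
    candidates = [i for i in range(len(AS.mirna_ids)) if AS.values[i, j] == 0]
    order = sorted(candidates, key=lambda i: (-col[i], i))[:top_k]
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "miRNA": [AS.mirna_ids[i] for i in order],
            "score": [float(col[i]) for i in order],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def xlsx_to_tsv(xlsx_path, tsv_path, sheet: int | str = 0) -> None:
    """Convert a 2-column spreadsheet to the canonical TSV interchange format."""
    frame = pd.read_excel(xlsx_path, sheet_name=sheet, header=None, dtype=str)
    frame = frame.dropna(how="all")
    frame.to_csv(tsv_path, sep="\t", index=False, header=False)
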