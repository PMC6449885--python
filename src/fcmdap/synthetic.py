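"""Seeded synthetic datasets with planted block structure.

The generator emulates the six inputs the predictor consumes: a
miRNA-target table, a disease-gene table, a binary association matrix,
family assignments, genomic coordinates and MeSH-style tree numbers.
miRNAs are partitioned into blocks and diseases into matching groups;
within a block, miRNAs draw targets from a shared mRNA pool (so their
mutual-information similarity is high), diseases of the paired group
share interaction genes and sit as siblings in the generated DAG, and
associations are preferentially placed inside block/group pairs.  A
fraction of blocks is additionally marked as a miRNA family and placed
as a genomic cluster, coupling all three signal channels the method
exploits; each channel can be disabled independently.

All randomness flows from one integer seed; each component draws from a
sub-stream keyed by its name, so regenerating with the same seed and
config is bit-identical and adding a component never perturbs others.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import (
    AssociationMatrix,
    CoordinateRecord,
    CoordinateTable,
    InteractionTable,
)

__all__ = ["SyntheticConfig", "DatasetBundle", "toy10_fixture", "generate", "export"]


@dataclass
class SyntheticConfig:
    """Sizes and effect parameters of the planted-structure generator."""

    n_mirnas: int = 50
    n_diseases: int = 20
    n_mrnas: int = 200
    n_genes: int = 150
    n_blocks: int = 5
    target_overlap_within_block: float = 0.7
    association_density: float = 0.15
    family_rate: float = 0.5
    cluster_rate: float = 0.5
    noise_rate: float = 0.02
    targets_per_mirna: int = 10
    genes_per_disease: int = 8
    block_mrna_pool: int = 20
    block_gene_pool: int = 15

    def __post_init__(self) -> None:
        if self.n_blocks > min(self.n_mirnas, self.n_diseases):
            raise ValueError("more blocks than miRNAs or diseases")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if not 0 <= self.target_overlap_within_block <= 1:
            raise ValueError("target_overlap_within_block must lie in [0, 1]")
        if not 0 < self.association_density < 1:
            raise ValueError("association_density must lie in (0, 1)")


@dataclass
class DatasetBundle:
    """All generated inputs plus the planted ground truth."""

    mirna_targets: InteractionTable
    disease_genes: InteractionTable
    associations: AssociationMatrix
    family: list[tuple[str, str]]  # (miRNA, family id)
    coordinates: CoordinateTable
    mesh: list[tuple[str, str]]  # (disease, tree number)
    truth: dict
    seed: int | None = None
    config: SyntheticConfig | None = None


def _rng(seed: int, component: str) -> np.random.Generator:
    """Named sub-stream: stable under addition of other components."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(component.encode())])
    )


def toy10_fixture() -> DatasetBundle:
    """The fixed ten-interaction worked example.

    Five miRNAs A..E over four target mRNAs (N = 10, counts g1:2 g2:4
    g3:3 g4:1), a two-member family {A, B} also placed within 20 kb on
    chr1, a three-disease chain DAG dR -> dA -> dB, a small gene table
    and a 5x3 association matrix.
    """
    target_pairs = {
        ("A", "g1"), ("A", "g2"),
        ("B", "g2"), ("B", "g3"),
        ("C", "g1"), ("C", "g3"), ("C", "g4"),
        ("D", "g2"), ("D", "g3"),
        ("E", "g2"),
    }
    gene_pairs = {
        ("dR", "h1"), ("dR", "h2"),
        ("dA", "h2"), ("dA", "h3"),
        ("dB", "h1"), ("dB", "h3"),
    }
    as_pairs = [("A", "dA"), ("B", "dA"), ("C", "dB"), ("D", "dR"), ("E", "dB")]
    coords = CoordinateTable(
        {
            "A": CoordinateRecord("chr1", 1000, 1085, "+"),
            "B": CoordinateRecord("chr1", 12000, 12085, "+"),
            "C": CoordinateRecord("chr2", 5000, 5085, "+"),
            "D": CoordinateRecord("chr1", 200000, 200085, "-"),
            "E": CoordinateRecord("chr3", 1000, 1085, "+"),
        }
    )
    mesh = [("dR", "C01"), ("dA", "C01.100"), ("dB", "C01.100.200")]
    return DatasetBundle(
        mirna_targets=InteractionTable(target_pairs),
        disease_genes=InteractionTable(gene_pairs),
        associations=AssociationMatrix.from_pairs(as_pairs),
        family=[("A", "fam1"), ("B", "fam1")],
        coordinates=coords,
        mesh=mesh,
        truth={"family_blocks": [0], "note": "fixed worked example"},
    )


def _draw_profile(
    rng: np.random.Generator,
    pool: np.ndarray,
    universe: list[str],
    size: int,
    overlap: float,
) -> set[str]:
    out: set[str] = set()
    for _ in range(size):
        if pool.size and rng.random() < overlap:
            out.add(str(rng.choice(pool)))
        else:
            out.add(universe[rng.integers(len(universe))])
    return out


def generate(seed: int, config: SyntheticConfig | None = None) -> DatasetBundle:
    """Generate a planted-signal dataset bundle from one integer seed."""
    cfg = config or SyntheticConfig()
    mirnas = [f"mir-{i+1:03d}" for i in range(cfg.n_mirnas)]
    diseases = [f"disease-{j+1:02d}" for j in range(cfg.n_diseases)]
    mrnas = [f"mrna-{k+1:03d}" for k in range(cfg.n_mrnas)]
    genes = [f"gene-{k+1:03d}" for k in range(cfg.n_genes)]
    m_block = np.array([i % cfg.n_blocks for i in range(cfg.n_mirnas)])
    d_group = np.array([j % cfg.n_blocks for j in range(cfg.n_diseases)])

    # miRNA-target interactions: block-shared pools + background draws
    rng = _rng(seed, "mirna_targets")
    pools = [
        rng.choice(mrnas, size=min(cfg.block_mrna_pool, cfg.n_mrnas), replace=False)
        for _ in range(cfg.n_blocks)
    ]
    target_pairs: set[tuple[str, str]] = set()
    for i, m in enumerate(mirnas):
        prof = _draw_profile(
            rng, pools[m_block[i]], mrnas, cfg.targets_per_mirna,
            cfg.target_overlap_within_block,
        )
        target_pairs.update((m, t) for t in prof)

    # disease-gene interactions, same scheme
    rng = _rng(seed, "disease_genes")
    gpools = [
        rng.choice(genes, size=min(cfg.block_gene_pool, cfg.n_genes), replace=False)
        for _ in range(cfg.n_blocks)
    ]
    gene_pairs: set[tuple[str, str]] = set()
    for j, d in enumerate(diseases):
        prof = _draw_profile(
            rng, gpools[d_group[j]], genes, cfg.genes_per_disease,
            cfg.target_overlap_within_block,
        )
        gene_pairs.update((d, g) for g in prof)

    # associations: placed only inside block/group pairs; cross-block
    # associations arise solely from the noise channel.  The within-block
    # probability is calibrated so the matrix density lands on the
    # configured value after noise flips.
    rng = _rng(seed, "associations")
    within = m_block[:, None] == d_group[None, :]
    f_in = within.mean()
    nu = cfg.noise_rate
    if nu >= 0.5:
        q = cfg.association_density  # flips dominate; calibration degenerate
    else:
        q = (cfg.association_density - nu) / (1.0 - 2.0 * nu)
    p_in = min(1.0, max(0.0, q) / f_in)
    prob = np.where(within, p_in, 0.0)
    values = (rng.random(prob.shape) < prob).astype(np.int8)
    noise = _rng(seed, "noise")
    flip = noise.random(values.shape) < cfg.noise_rate
    values = np.where(flip, 1 - values, values).astype(np.int8)
    # every entity keeps at least one association so degrees stay >= 1
    fix = _rng(seed, "degree_fix")
    for i in np.where(values.sum(axis=1) == 0)[0]:
        own = np.where(d_group == m_block[i])[0]
        values[i, own[fix.integers(own.size)]] = 1
    for j in np.where(values.sum(axis=0) == 0)[0]:
        own = np.where(m_block == d_group[j])[0]
        values[own[fix.integers(own.size)], j] = 1

    # reorder diseases to row-major first appearance so a pair-table
    # round trip reproduces the bundle exactly
    order: list[int] = []
    for i in range(cfg.n_mirnas):
        for j in np.nonzero(values[i])[0]:
            if j not in order:
                order.append(int(j))
    order += [j for j in range(cfg.n_diseases) if j not in order]
    values = values[:, order]
    diseases = [diseases[j] for j in order]
    d_group = d_group[order]
    AS = AssociationMatrix(values, mirnas, diseases)

    # family / cluster channels on a random subset of blocks
    rng = _rng(seed, "family")
    family_blocks = [
        b for b in range(cfg.n_blocks) if rng.random() < cfg.family_rate
    ]
    family = [
        (mirnas[i], f"fam-{m_block[i]+1}")
        for i in range(cfg.n_mirnas)
        if m_block[i] in family_blocks
    ]
    rng = _rng(seed, "cluster")
    cluster_blocks = [
        b for b in range(cfg.n_blocks) if rng.random() < cfg.cluster_rate
    ]
    coords = CoordinateTable()
    spacing, length = 1500, 80  # all block members pairwise within 20 kb
    far = 1_000_000
    offset = {b: 0 for b in range(cfg.n_blocks)}
    for i, m in enumerate(mirnas):
        b = m_block[i]
        k = offset[b]
        offset[b] += 1
        if b in cluster_blocks:
            start = 10_000 + k * (spacing + length)
            coords[m] = CoordinateRecord(f"chr{b+1}", start, start + length, "+")
        else:
            start = 10_000 + k * far
            coords[m] = CoordinateRecord(f"chrU{b+1}", start, start + length, "+")

    # MeSH-style DAG: one root per group, group members as siblings
    mesh: list[tuple[str, str]] = []
    for b in range(cfg.n_blocks):
        mesh.append((f"disease-group-{b+1}", f"C{b+1:02d}"))
    rank_in_group = {b: 0 for b in range(cfg.n_blocks)}
    for j, d in enumerate(diseases):
        b = int(d_group[j])
        mesh.append((d, f"C{b+1:02d}.{100 + rank_in_group[b]}"))
        rank_in_group[b] += 1

    truth = {
        "mirna_blocks": {m: int(b) for m, b in zip(mirnas, m_block)},
        "disease_groups": {d: int(b) for d, b in zip(diseases, d_group)},
        "family_blocks": family_blocks,
        "cluster_blocks": cluster_blocks,
    }
    return DatasetBundle(
        mirna_targets=InteractionTable(target_pairs),
        disease_genes=InteractionTable(gene_pairs),
        associations=AS,
        family=family,
        coordinates=coords,
        mesh=mesh,
        truth=truth,
        seed=seed,
        config=cfg,
    )


def _write_pairs(path: Path, pairs, header: tuple[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#{header[0]}\t{header[1]}\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def export(bundle: DatasetBundle, directory) -> dict[str, str]:
    """Write every bundle component in the formats the readers consume.

    Returns the manifest (seed, config, per-file sha256 checksums), which
    is also written as ``manifest.json``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_pairs(
        d / "mirna_targets.tsv", sorted(bundle.mirna_targets.pairs),
        ("miRNA", "mRNA"),
    )
    _write_pairs(
        d / "disease_genes.tsv", sorted(bundle.disease_genes.pairs),
        ("disease", "gene"),
    )
    _write_pairs(
        d / "associations.tsv", bundle.associations.to_pairs(),
        ("miRNA", "disease"),
    )
    _write_pairs(d / "family.tsv", bundle.family, ("miRNA", "family"))
    _write_pairs(d / "mesh.tsv", bundle.mesh, ("disease", "tree_number"))
    with open(d / "mirnas.gff3", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in bundle.associations.mirna_ids:
            if m not in bundle.coordinates:
                continue
            r = bundle.coordinates[m]
            fh.write(
                f"{r.chrom}\t.\tmiRNA\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={m};Name={m}\n"
            )
    files = {}
    for name in (
        "mirna_targets.tsv", "disease_genes.tsv", "associations.tsv",
        "family.tsv", "mesh.tsv", "mirnas.gff3",
    ):
        files[name] = hashlib.sha256((d / name).read_bytes()).hexdigest()
    manifest = {
        "seed": bundle.seed,
        "config": asdict(bundle.config) if bundle.config else None,
        "files": files,
    }
    with open(d / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
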