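"""Ortholog counting and conservation summaries.

Conservation is measured operationally by ortholog number: the more panel
species in which a gene has at least one ortholog, the more conserved it
is. This module provides per-gene counts, the normalized count histogram,
per-species totals for a gene set, extraction of the clade-conserved
subset (present in every species of a clade), direction partitioning, and
set-level summary statistics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import GeneSet, OrthologMatrix, SpeciesPanel, ValidationError

__all__ = [
    "ortholog_count_per_gene",
    "count_distribution",
    "per_species_set_counts",
    "clade_conserved_subset",
    "partition_by_direction",
    "set_statistics",
]


def ortholog_count_per_gene(matrix: OrthologMatrix) -> np.ndarray:
    """Integer ortholog count per gene, in matrix gene order."""
    if matrix.n_genes == 0:
        raise ValidationError("empty ortholog matrix")
    return matrix.counts()


def count_distribution(counts: Sequence[int], n_species: int) -> np.ndarray:
    """Normalized histogram over bins 0..n_species (fractions sum to 1)."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValidationError("no counts supplied")
    if counts.min() < 0 or counts.max() > n_species:
        raise ValidationError(f"count outside [0, {n_species}]")
    hist = np.bincount(counts, minlength=n_species + 1).astype(float)
    return hist / hist.sum()


def per_species_set_counts(matrix: OrthologMatrix, gene_set: GeneSet) -> np.ndarray:
    """For each counting species, the number of set genes with an ortholog there."""
    idx = matrix.gene_indices(gene_set.genes)
    if idx.size == 0:
        return np.zeros(matrix.n_species, dtype=np.int64)
    return matrix.presence[idx].sum(axis=0).astype(np.int64)


def clade_conserved_subset(
    matrix: OrthologMatrix,
    gene_set: GeneSet,
    panel: SpeciesPanel,
    clade: str,
    quorum: float = 1.0,
) -> GeneSet:
    """Subset of the set conserved across a clade.

    Default quorum 1.0 requires presence in every clade species
    (intersection); smaller quorums relax to a fraction of the clade.
    """
    if not 0.0 < quorum <= 1.0:
        raise ValidationError("quorum must lie in (0, 1]")
    members = panel.clade_members(clade)
    col = {s: j for j, s in enumerate(matrix.species)}
    missing = [s for s in members if s not in col]
    if missing:
        raise ValidationError(f"clade species {missing[0]!r} not in matrix")
    cols = np.array([col[s] for s in members])
    idx = matrix.gene_indices(gene_set.genes)
    hits = matrix.presence[np.ix_(idx, cols)].sum(axis=1)
    need = int(np.ceil(quorum * len(members)))
    keep = [g for g, h in zip(gene_set.genes, hits) if h >= need]
    dirs = gene_set.direction_of
    return GeneSet(
        name=f"{gene_set.name}_conserved_{clade}",
        genes=tuple(keep),
        direction_of={g: dirs[g] for g in keep if g in dirs} if dirs else None,
        description=f"{gene_set.name} genes present in >= {need}/{len(members)} {clade} species",
    )


def partition_by_direction(gene_set: GeneSet) -> tuple[GeneSet, GeneSet]:
    """Split a set into its up- and down-regulated halves (disjoint cover)."""
    dirs = gene_set.direction_of or {}
    unlabeled = [g for g in gene_set.genes if g not in dirs]
    if unlabeled:
        raise ValidationError(f"gene {unlabeled[0]!r} has no direction label")
    up = tuple(g for g in gene_set.genes if dirs[g] == "up")
    down = tuple(g for g in gene_set.genes if dirs[g] == "down")
    return (
        GeneSet(f"{gene_set.name}_up", up, {g: "up" for g in up}, gene_set.description),
        GeneSet(f"{gene_set.name}_down", down, {g: "down" for g in down}, gene_set.description),
    )


def set_statistics(
    matrix: OrthologMatrix, gene_set: GeneSet, ddof: int = 0
) -> dict[str, float]:
    """Total, mean and SD of ortholog counts over a (mapped) gene set.

    SD uses the population divisor n by default (``ddof=0``).
    """
    idx = matrix.gene_indices(gene_set.genes)
    if idx.size == 0:
        raise ValidationError(f"set {gene_set.name!r} is empty")
    counts = matrix.presence[idx].sum(axis=1).astype(float)
    return {
        "set": gene_set.name,
        "set_size": int(idx.size),
        "total_orthologs": int(counts.sum()),
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=ddof)),
    }
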