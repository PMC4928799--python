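"""Synthetic data generator with known planted structure.

Emulates the study population this pipeline was designed for: a honey-bee
gene universe scored for ortholog presence across a 54-species counting
panel (17 arthropods, 10 placental mammals, other metazoa, plus a yeast
outgroup control). Genes fall into three conservation classes — lineage
unique, clade conserved, ubiquitous — which reproduces the trimodal
ortholog-count histogram (modes near 0, the focal-clade size, and ~50)
seen in real cross-metazoan scans.

The model is deliberately simple: class membership is i.i.d. across genes
and presence is an independent Bernoulli per species, with a within-clade
probability for the clade-conserved class and an outside probability for
everything else. No phylogenetic correlation is simulated; downstream
stages only consume per-gene counts and clade blocks.

All randomness flows from one seed through named substreams so each
artifact (matrix, sets, annotation) can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import GeneSet, OrthologMatrix, SpeciesPanel, ValidationError

__all__ = [
    "SyntheticConfig",
    "generate_species_panel",
    "generate_ortholog_matrix",
    "generate_gene_sets",
    "generate_annotation",
    "DEFAULT_CLADE_SPEC",
]

# 54 counting species: 53 metazoa + yeast outgroup; the reference bee is a
# separate, non-counting column.
DEFAULT_CLADE_SPEC: tuple[tuple[str, int], ...] = (
    ("arthropoda", 17),
    ("eutheria", 10),
    ("other", 26),
    ("yeast", 1),
)

_STREAMS = {"classes": 0, "matrix": 1, "sets": 2, "annotation": 3, "panel": 4}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    class_fractions are the proportions of (unique, clade-conserved,
    ubiquitous) genes; presence_probs gives, per class, the (within focal
    clade, outside) per-species presence probability. The defaults target
    the trimodal histogram of a ~7.5k-gene microarray universe.
    """

    n_genes: int = 7462
    clade_spec: tuple[tuple[str, int], ...] = DEFAULT_CLADE_SPEC
    class_fractions: tuple[float, float, float] = (0.05, 0.35, 0.60)
    presence_probs: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),  # unique
        (0.95, 0.02),  # clade-conserved
        (0.93, 0.93),  # ubiquitous
    )
    focal_clade: str = "arthropoda"
    outgroup_clade: Optional[str] = "yeast"
    outgroup_presence_prob: float = 0.5
    set_sizes: tuple[int, ...] = (275, 899, 512, 308, 180, 22, 248, 132)
    enrichment_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValidationError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValidationError("class_fractions must be non-negative")
        for pin, pout in self.presence_probs:
            if not (0.0 <= pin <= 1.0 and 0.0 <= pout <= 1.0):
                raise ValidationError("presence probabilities must lie in [0, 1]")
        if not 0.0 <= self.outgroup_presence_prob <= 1.0:
            raise ValidationError("outgroup_presence_prob must lie in [0, 1]")
        for size in self.set_sizes:
            if size < 1:
                raise ValidationError("set sizes must be >= 1")
            if size > self.n_genes:
                raise ValidationError(f"set size {size} exceeds n_genes={self.n_genes}")


def generate_species_panel(
    clade_spec: Sequence[tuple[str, int]],
    reference_species: str = "apis_mellifera",
) -> SpeciesPanel:
    """Build a deterministic panel with one species slot per request.

    Species are named ``<clade>_<i>`` in clade order, which also fixes the
    display order; the reference organism is excluded from counting columns.
    """
    names = [c for c, _ in clade_spec]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate clade name in clade_spec")
    species: list[str] = []
    clade_of: dict[str, str] = {}
    for clade, n in clade_spec:
        if n < 1:
            raise ValidationError(f"clade {clade!r} requests {n} species")
        for i in range(1, n + 1):
            s = f"{clade}_{i:02d}"
            species.append(s)
            clade_of[s] = clade
    return SpeciesPanel(tuple(species), clade_of, reference_species=reference_species)


def _species_prob_matrix(config: SyntheticConfig, panel: SpeciesPanel) -> np.ndarray:
    """Per-class, per-species presence probabilities, shape (3, S)."""
    S = len(panel.species)
    probs = np.empty((3, S), dtype=float)
    for ci, (p_in, p_out) in enumerate(config.presence_probs):
        for si, sp in enumerate(panel.species):
            clade = panel.clade_of[sp]
            p = p_in if clade == config.focal_clade else p_out
            # outgroup control: even ubiquitous genes are present there with
            # reduced probability (deep split from the rest of the panel)
            if config.outgroup_clade is not None and clade == config.outgroup_clade:
                p = min(p, config.outgroup_presence_prob)
            probs[ci, si] = p
    return probs


def expected_class_means(config: SyntheticConfig) -> np.ndarray:
    """Expected ortholog count per conservation class (binomial mean Σ_s p_s)."""
    panel = generate_species_panel(config.clade_spec)
    return _species_prob_matrix(config, panel).sum(axis=1)


def generate_ortholog_matrix(config: SyntheticConfig) -> OrthologMatrix:
    """Draw a presence matrix from the class-mixture Bernoulli model."""
    panel = generate_species_panel(config.clade_spec)
    rng_cls = _substream(config.seed, "classes")
    rng_mat = _substream(config.seed, "matrix")
    classes = rng_cls.choice(3, size=config.n_genes, p=np.asarray(config.class_fractions))
    probs = _species_prob_matrix(config, panel)  # (3, S)
    u = rng_mat.random((config.n_genes, len(panel.species)))
    presence = u < probs[classes]
    genes = tuple(f"g{i:05d}" for i in range(config.n_genes))
    return OrthologMatrix(genes, panel.species, presence)


def gene_classes(config: SyntheticConfig) -> np.ndarray:
    """The conservation class of each generated gene (same substream as the matrix)."""
    rng_cls = _substream(config.seed, "classes")
    return rng_cls.choice(3, size=config.n_genes, p=np.asarray(config.class_fractions))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, log_weights: np.ndarray, size: int
) -> np.ndarray:
    # Gumbel-key trick: top-k of log w + Gumbel noise is an exact draw from
    # successive (Plackett-Luce) sampling without replacement.
    keys = log_weights + rng.gumbel(size=log_weights.shape)
    if size == log_weights.shape[0]:
        order = np.argsort(-keys)
        return order
    top = np.argpartition(-keys, size)[:size]
    return top[np.argsort(-keys[top])]


def generate_gene_sets(
    matrix: OrthologMatrix,
    set_sizes: Sequence[int],
    enrichment_beta: float = 0.0,
    seed: int = 0,
) -> list[GeneSet]:
    """Sample gene sets with conservation-dependent inclusion weights.

    Each set is drawn without replacement with per-gene weight
    exp(beta * ortholog_count): beta = 0 is a uniform null, beta > 0 plants
    enrichment in widely conserved genes, beta < 0 plants depletion. Each
    gene gets a random up/down regulation label.
    """
    rng = _substream(seed, "sets")
    counts = matrix.counts().astype(float)
    sets: list[GeneSet] = []
    for j, size in enumerate(set_sizes):
        if size > matrix.n_genes:
            raise ValidationError(f"set size {size} exceeds population {matrix.n_genes}")
        if size < 1:
            raise ValidationError("set size must be >= 1")
        idx = _weighted_sample_without_replacement(rng, enrichment_beta * counts, size)
        genes = tuple(matrix.genes[i] for i in sorted(idx))
        directions = rng.choice(["up", "down"], size=size)
        sets.append(
            GeneSet(
                name=f"set{j + 1}_n{size}",
                genes=genes,
                direction_of=dict(zip(genes, directions.tolist())),
                description=f"synthetic set, beta={enrichment_beta:g}",
            )
        )
    return sets


def generate_annotation(
    genes: Sequence[str],
    n_terms: int,
    planted_terms: Optional[Mapping[str, Sequence[str]]] = None,
    seed: int = 0,
    min_term_size: int = 5,
    max_term_size: int = 50,
    parent_edges: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[dict[str, tuple[str, ...]], tuple[tuple[str, str], ...]]:
    """Random term→gene annotation plus an acyclic term hierarchy.

    ``planted_terms`` maps a term id to an exact gene membership, letting a
    test plant a term that covers precisely a study set. Random terms draw
    their genes uniformly. Unless ``parent_edges`` is supplied, the parent
    table is a random tree (child listed before parent lookup guarantees
    acyclicity); supplied edges are validated for cycles.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    genes = list(genes)
    rng = _substream(seed, "annotation")
    term_map: dict[str, tuple[str, ...]] = {}
    for t in range(n_terms):
        size = int(rng.integers(min_term_size, min(max_term_size, len(genes)) + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        term_map[f"t{t:04d}"] = tuple(genes[i] for i in sorted(members))
    if planted_terms:
        for term, members in planted_terms.items():
            term_map[term] = tuple(members)
    term_ids = list(term_map)
    if parent_edges is not None:
        edges = tuple(parent_edges)
        _check_acyclic(edges)
    else:
        edges_list: list[tuple[str, str]] = []
        for i in range(1, len(term_ids)):
            parent = term_ids[int(rng.integers(0, i))]
            edges_list.append((term_ids[i], parent))
        edges = tuple(edges_list)
    return term_map, edges


def _check_acyclic(edges: Sequence[tuple[str, str]]) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("cycle requested in parent table")


def exact_enumeration_mean(counts: Sequence[float], size: int, beta: float) -> float:
    """Expected mean ortholog count of a weighted draw, by exhaustive enumeration.

    Enumerates every ordered without-replacement sequence under the
    Plackett-Luce model (the model the Gumbel-key sampler realises).
    Intended as an oracle for tiny populations only.
    """
    from itertools import permutations

    counts = np.asarray(counts, dtype=float)
    w = np.exp(beta * counts)
    n = len(counts)
    if math.perm(n, size) > 200_000:
        raise ValidationError("population too large for exact enumeration")
    total = 0.0
    for seq in permutations(range(n), size):
        p = 1.0
        rem = w.sum()
        for i in seq:
            p *= w[i] / rem
            rem -= w[i]
        total += p * counts[list(seq)].mean()
    return total
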