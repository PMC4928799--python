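"""Core containers shared across the pipeline.

The analysis works on three objects: a boolean gene-by-species ortholog
presence matrix, a species panel carrying clade labels and a display order,
and named gene sets (optionally with per-gene up/down regulation labels).
Everything downstream — ortholog counting, resampling nulls, clade
comparisons, term enrichment — consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SpeciesPanel",
    "GeneSet",
    "IdMap",
    "OrthologMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object or file violates its contract."""


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered counting-species panel with clade labels.

    ``species`` is the display order (e.g. by evolutionary distance from the
    reference organism). The reference organism itself is never a counting
    column: a gene trivially has itself as an ortholog.
    """

    species: tuple[str, ...]
    clade_of: Mapping[str, str]
    reference_species: str = "reference"

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species identifiers in panel")
        if self.reference_species in self.species:
            raise ValidationError(
                f"reference species {self.reference_species!r} must not be a counting species"
            )
        missing = [s for s in self.species if s not in self.clade_of]
        if missing:
            raise ValidationError(f"species without clade label: {missing[0]!r}")

    def clade_members(self, clade: str) -> tuple[str, ...]:
        members = tuple(s for s in self.species if self.clade_of[s] == clade)
        if not members:
            raise ValidationError(f"clade {clade!r} is unknown or empty")
        return members

    @property
    def clades(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(self.clade_of[s], None)
        return tuple(seen)


@dataclass(frozen=True)
class GeneSet:
    """A named list of genes, optionally with per-gene regulation direction."""

    name: str
    genes: tuple[str, ...]
    direction_of: Optional[Mapping[str, str]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate gene identifiers in set {self.name!r}")
        if self.direction_of is not None:
            extra = set(self.direction_of) - set(self.genes)
            if extra:
                raise ValidationError(
                    f"direction labels for genes not in set {self.name!r}: {sorted(extra)[:3]}"
                )
            bad = {d for d in self.direction_of.values() if d not in ("up", "down")}
            if bad:
                raise ValidationError(f"invalid direction labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class IdMap:
    """Many-to-one map from platform IDs to ortholog-database IDs."""

    pairs: Mapping[str, str]
    n_ambiguous_dropped: int = 0

    def get(self, source: str) -> Optional[str]:
        return self.pairs.get(source)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class OrthologMatrix:
    """Boolean gene x counting-species ortholog presence matrix.

    Presence, not in-paralog multiplicity, is stored: a gene contributes at
    most one ortholog count per species.
    """

    genes: tuple[str, ...]
    species: tuple[str, ...]
    presence: np.ndarray  # bool, shape (n_genes, n_species)
    _gene_index: dict = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pres = np.asarray(self.presence, dtype=bool)
        if pres.shape != (len(self.genes), len(self.species)):
            raise ValidationError(
                f"presence shape {pres.shape} != ({len(self.genes)}, {len(self.species)})"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers in matrix")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species identifiers in matrix")
        object.__setattr__(self, "presence", pres)
        object.__setattr__(self, "_gene_index", {g: i for i, g in enumerate(self.genes)})

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def counts(self) -> np.ndarray:
        """Per-gene ortholog count (number of species with presence)."""
        return self.presence.sum(axis=1).astype(np.int64)

    def count_of(self, gene: str) -> int:
        return int(self.presence[self._gene_index[gene]].sum())

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        idx = self._gene_index
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"gene {missing[0]!r} not in ortholog matrix")
        return np.fromiter((idx[g] for g in genes), dtype=np.int64, count=len(genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index
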