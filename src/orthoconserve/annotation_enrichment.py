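"""Term over-representation of a study set against a background population.

Given a term→gene annotation map, each term annotating at least one study
gene is tested with the hypergeometric upper tail

    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n)

or its conservative EASE variant (one study hit removed before taking the
tail, p = 1 when k <= 1). Benjamini-Hochberg correction is applied across
all terms tested in one run; up-, down-regulated and combined study sets
are three independent test families. Ancestor closure over the term
hierarchy produces the tree table used for reporting: each enriched term
plus all its ancestors, each row carrying parent/child links and a
significance class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
from scipy import stats

from .datatypes import ValidationError
from .resampling import bh_adjust

__all__ = [
    "TermEnrichmentResult",
    "term_overrepresentation",
    "ancestor_closure",
]


@dataclass(frozen=True)
class TermEnrichmentResult:
    term: str
    k: int  # study hits
    K: int  # population hits
    n: int  # study size (within background)
    N: int  # background size
    p_raw: float
    p_bh: float
    direction_context: str = "combined"

    def __post_init__(self) -> None:
        assert 0 <= self.k <= min(self.K, self.n)


def _tail(N: int, K: int, n: int, k_from: int) -> float:
    """Hypergeometric upper tail P(X >= k_from)."""
    if k_from <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k_from - 1, N, K, n))


def term_overrepresentation(
    study_set: Sequence[str],
    population: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    method: str = "hypergeometric",
    background: str = "annotated",
    direction_context: str = "combined",
) -> list[TermEnrichmentResult]:
    """Test every term hitting the study set for over-representation.

    ``background='annotated'`` restricts the universe to population genes
    carrying at least one term (the usual enrichment-tool default);
    ``'all'`` uses the full population. Terms with zero study hits are not
    tested. Results are BH-corrected as one family.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValidationError(f"unknown method {method!r}")
    if background not in ("annotated", "all"):
        raise ValidationError(f"unknown background {background!r}")
    pop = set(population)
    study = set(study_set)
    missing = study - pop
    if missing:
        raise ValidationError(f"study gene {sorted(missing)[0]!r} absent from population")
    annotated = set()
    for genes in term_map.values():
        annotated.update(genes)
    universe = (pop & annotated) if background == "annotated" else pop
    study_u = study & universe
    N, n = len(universe), len(study_u)
    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe
        K = len(members)
        k = len(members & study_u)
        if k == 0:
            continue
        if method == "ease":
            p = 1.0 if k <= 1 else _tail(N, K, n, k - 1)
        else:
            p = _tail(N, K, n, k)
        rows.append((term, k, K, p))
    adj = bh_adjust([r[3] for r in rows])
    return [
        TermEnrichmentResult(term, k, K, n, N, p, float(p_bh), direction_context)
        for (term, k, K, p), p_bh in zip(rows, adj)
    ]


@dataclass(frozen=True)
class ClosureRow:
    term: str
    significance: str  # 'strong' (<=0.01), 'enriched' (<=0.05), 'parent-only'
    p_bh: Optional[float]
    parents: tuple[str, ...]
    children: tuple[str, ...]


def ancestor_closure(
    enriched: Sequence[TermEnrichmentResult],
    parent_edges: Sequence[tuple[str, str]],
    alpha_strong: float = 0.01,
    alpha: float = 0.05,
) -> list[ClosureRow]:
    """Enriched terms plus all their ancestors in the term hierarchy.

    Ancestors that are not themselves enriched are flagged 'parent-only'.
    The output is closed under the child→parent relation and free of
    duplicates; a cycle in the parent table is an error.
    """
    g = nx.DiGraph()
    g.add_edges_from(parent_edges)  # edge child -> parent
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("cycle detected in term parent table")
    p_of = {r.term: r.p_bh for r in enriched}
    keep: set[str] = set(p_of)
    for term in p_of:
        if term in g:
            keep |= nx.descendants(g, term)  # ancestors along child->parent edges
    rows: list[ClosureRow] = []
    for term in sorted(keep):
        p = p_of.get(term)
        if p is None:
            sig = "parent-only"
        elif p <= alpha_strong:
            sig = "strong"
        elif p <= alpha:
            sig = "enriched"
        else:
            sig = "not-significant"
        parents = tuple(sorted(set(g.successors(term)) & keep)) if term in g else ()
        children = tuple(sorted(set(g.predecessors(term)) & keep)) if term in g else ()
        rows.append(ClosureRow(term, sig, p, parents, children))
    return rows
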