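"""Resampling nulls for conservation enrichment of gene sets.

The central statistic: for a set of n genes, draw random sets of the same
size uniformly without replacement from the full gene population, score
each draw, and report the one-sided tail fraction. Two observed statistics
are supported — the mean ortholog count of the set, and the per-species
total ortholog count (one resampling pass scores every species at once).
Both tails use closed inequalities (>= for enrichment, <= for depletion),
so p-values are integer multiples of 1/R and p_enrich + p_deplete >= 1.

When C(N, n) is small the test switches automatically to exhaustive
enumeration, which the sampler must agree with in the large-R limit. A
zero tail count is reported as p = 0 with ``below_resolution`` set —
printed as "< 1/R" — and floored at 1/R before any log-based combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .conservation import per_species_set_counts
from .datatypes import GeneSet, OrthologMatrix, ValidationError

__all__ = [
    "EnrichmentResult",
    "permutation_test_mean",
    "permutation_test_per_species",
    "bh_adjust",
    "format_pvalue",
]

DEFAULT_RESAMPLES = 1_000_000
DEFAULT_EXACT_THRESHOLD = 20_000
_CHUNK = 256


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided resampling p-values for a single observed statistic."""

    observed: float
    null_mean: float
    p_enrich: float
    p_deplete: float
    n_resamples: int
    seed: Optional[int]
    below_resolution: bool = False
    exact: bool = False
    statistic: str = "mean"
    species: Optional[str] = None


def format_pvalue(result: EnrichmentResult) -> str:
    """Render a resolution-limited zero tail as '< 1/R'."""
    if result.below_resolution:
        return f"< {1.0 / result.n_resamples:g}"
    return format(result.p_enrich, ".6g")


def floor_pvalue(result: EnrichmentResult) -> float:
    """p_enrich floored at the test's resolution, safe for log combination."""
    return max(result.p_enrich, 1.0 / result.n_resamples)


def _set_sum(matrix: OrthologMatrix, gene_set: GeneSet) -> tuple[np.ndarray, int]:
    idx = matrix.gene_indices(gene_set.genes)
    if idx.size == 0 or idx.size > matrix.n_genes:
        raise ValidationError("set size must be in [1, n_genes]")
    counts = matrix.counts()
    return counts, int(counts[idx].sum())


def permutation_test_mean(
    matrix: OrthologMatrix,
    gene_set: GeneSet,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> EnrichmentResult:
    """Resampling p-value for the set's mean ortholog count.

    Mean comparisons reduce to integer sum comparisons at fixed set size,
    so ties are handled exactly. Enumerates all C(N, n) subsets instead of
    sampling when that count is within ``exact_threshold``.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    counts, obs_sum = _set_sum(matrix, gene_set)
    n = len(gene_set.genes)
    N = matrix.n_genes
    if math.comb(N, n) <= exact_threshold:
        sums = np.fromiter(
            (sum(c) for c in combinations(counts.tolist(), n)),
            dtype=np.int64,
            count=math.comb(N, n),
        )
        R = sums.size
        exact = True
    else:
        sums = _sample_sums(counts, n, n_resamples, seed)
        R = n_resamples
        exact = False
    ge = int((sums >= obs_sum).sum())
    le = int((sums <= obs_sum).sum())
    return EnrichmentResult(
        observed=obs_sum / n,
        null_mean=float(sums.mean()) / n,
        p_enrich=ge / R,
        p_deplete=le / R,
        n_resamples=R,
        seed=None if exact else seed,
        below_resolution=(ge == 0 or le == 0),
        exact=exact,
        statistic="mean",
    )


def _sample_sums(counts: np.ndarray, n: int, R: int, seed: int) -> np.ndarray:
    """Sums of R uniform without-replacement samples of size n, chunked."""
    rng = np.random.default_rng(seed)
    N = counts.size
    counts_f = counts.astype(np.float64)
    out = np.empty(R, dtype=np.int64)
    done = 0
    while done < R:
        chunk = min(_CHUNK, R - done)
        keys = rng.random((chunk, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[done : done + chunk] = counts_f[idx].sum(axis=1).astype(np.int64)
        done += chunk
    return out


def permutation_test_per_species(
    matrix: OrthologMatrix,
    gene_set: GeneSet,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> list[EnrichmentResult]:
    """Per-species resampling p-values for the set's total ortholog count.

    One resampled set scores all species in one pass (the null draws are
    shared across species, not independent per species).
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    observed = per_species_set_counts(matrix, gene_set)
    n = len(gene_set.genes)
    N = matrix.n_genes
    if n == 0 or n > N:
        raise ValidationError("set size must be in [1, n_genes]")
    pres = matrix.presence.astype(np.int16)
    if math.comb(N, n) <= exact_threshold:
        totals = np.array(
            [pres[list(c)].sum(axis=0) for c in combinations(range(N), n)], dtype=np.int64
        )
        R = totals.shape[0]
        exact = True
        seed_out = None
    else:
        rng = np.random.default_rng(seed)
        totals = np.empty((n_resamples, matrix.n_species), dtype=np.int64)
        done = 0
        while done < n_resamples:
            chunk = min(_CHUNK, n_resamples - done)
            keys = rng.random((chunk, N))
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
            totals[done : done + chunk] = pres[idx].sum(axis=1)
            done += chunk
        R = n_resamples
        exact = False
        seed_out = seed
    results = []
    for j, sp in enumerate(matrix.species):
        ge = int((totals[:, j] >= observed[j]).sum())
        le = int((totals[:, j] <= observed[j]).sum())
        results.append(
            EnrichmentResult(
                observed=float(observed[j]),
                null_mean=float(totals[:, j].mean()),
                p_enrich=ge / R,
                p_deplete=le / R,
                n_resamples=R,
                seed=seed_out,
                below_resolution=(ge == 0 or le == 0),
                exact=exact,
                statistic="per_species_total",
                species=sp,
            )
        )
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
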