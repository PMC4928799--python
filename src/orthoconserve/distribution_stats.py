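"""Two-sample Kolmogorov-Smirnov test, Fisher's method, clade comparison.

The KS statistic D is the maximum gap between the two right-continuous
empirical CDFs, evaluated at every distinct pooled value — the convention
under which two samples with disjoint ranges give exactly D = 1. The tail
probability uses the classical asymptotic series with the small-sample
correction of Numerical Recipes:

    lambda = (sqrt(Ne) + 0.12 + 0.11 / sqrt(Ne)) * D,   Ne = n1*n2/(n1+n2)
    Q_KS(lambda) = 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lambda^2)

An exact permutation tail (all label reassignments when feasible, else a
seeded Monte Carlo) is provided for cross-checking but is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import SpeciesPanel, ValidationError

__all__ = [
    "KSResult",
    "ks_two_sample",
    "qks",
    "fisher_combine",
    "clade_comparison",
    "ks_permutation_p",
    "five_number_summary",
]


@dataclass(frozen=True)
class KSResult:
    D: float
    n1: int
    n2: int
    Ne: float
    lam: float
    P: float
    # pooled distinct values with both cumulative fractions (plot data)
    curve_values: np.ndarray
    curve_f1: np.ndarray
    curve_f2: np.ndarray


def qks(lam: float) -> float:
    """Asymptotic KS tail probability Q_KS(lambda).

    Alternating series truncated when a term falls below 1e-8 of the
    partial sum or j exceeds 100; clamped to [0, 1]; Q_KS(0) = 1.
    """
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    if lam == 0.0:
        return 1.0
    total = 0.0
    sign = 1.0
    prev_term = 0.0
    for j in range(1, 101):
        term = math.exp(-2.0 * j * j * lam * lam)
        total += sign * term
        # converged once terms are negligible against the sum or shrinking fast
        if term <= 1e-8 * abs(total) or term <= 0.001 * prev_term:
            return min(1.0, max(0.0, 2.0 * total))
        prev_term = term
        sign = -sign
    return 1.0  # series fails to converge only when the tail is effectively 1


def _ecdf_curves(x: np.ndarray, y: np.ndarray):
    pooled = np.unique(np.concatenate([x, y]))
    f1 = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    f2 = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return pooled, f1, f2


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample KS statistic with the asymptotic tail probability."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("samples must be finite")
    pooled, f1, f2 = _ecdf_curves(x, y)
    d = float(np.abs(f1 - f2).max())
    ne = x.size * y.size / (x.size + y.size)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    return KSResult(
        D=d, n1=int(x.size), n2=int(y.size), Ne=ne, lam=lam, P=qks(lam),
        curve_values=pooled, curve_f1=f1, curve_f2=f2,
    )


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi-square with 2k df.

    Resampling zeros must be floored at 1/R by the caller first.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if (p <= 0).any():
        raise ValidationError("p-values must be > 0 (floor resampling zeros at 1/R)")
    if (p > 1).any():
        raise ValidationError("p-values must be <= 1")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def five_number_summary(values: Sequence[float]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
    }


def clade_comparison(
    per_species_pvalues: Mapping[str, float],
    panel: SpeciesPanel,
    clade_a: str,
    clade_b: str,
) -> tuple[dict[str, dict[str, float]], KSResult]:
    """Boxplot five-number summaries per clade plus the KS test between them."""
    members_a = panel.clade_members(clade_a)
    members_b = panel.clade_members(clade_b)
    if set(members_a) & set(members_b):
        raise ValidationError(f"clades {clade_a!r} and {clade_b!r} overlap")
    va = [per_species_pvalues[s] for s in members_a]
    vb = [per_species_pvalues[s] for s in members_b]
    summaries = {clade_a: five_number_summary(va), clade_b: five_number_summary(vb)}
    return summaries, ks_two_sample(va, vb)


def _d_only(xs: np.ndarray, n1: int) -> float:
    # D for a pooled sorted-by-value arrangement given membership mask
    pooled = np.unique(xs)
    x = np.sort(xs[:n1])
    y = np.sort(xs[n1:])
    f1 = np.searchsorted(x, pooled, side="right") / n1
    f2 = np.searchsorted(y, pooled, side="right") / (xs.size - n1)
    return float(np.abs(f1 - f2).max())


def ks_permutation_p(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 20_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation tail P(D* >= D) under label exchange, for cross-checking.

    Enumerates every label reassignment when C(n1+n2, n1) is within
    ``exact_threshold``; otherwise a seeded Monte Carlo over n_perm
    reassignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = ks_two_sample(x, y).D
    pooled = np.concatenate([x, y])
    n1, ntot = x.size, pooled.size
    if math.comb(ntot, n1) <= exact_threshold:
        hits = 0
        total = 0
        for comb in combinations(range(ntot), n1):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(comb)] = True
            d = _d_only(np.concatenate([pooled[mask], pooled[~mask]]), n1)
            hits += d >= obs - 1e-12
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        hits += _d_only(perm, n1) >= obs - 1e-12
    return hits / n_perm
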