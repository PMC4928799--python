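"""Resampling-null correctness: enumeration oracles, calibration, BH."""

import math
from itertools import combinations

import numpy as np
import pytest

from orthoconserve.datatypes import GeneSet, OrthologMatrix, ValidationError
from orthoconserve.resampling import (
    bh_adjust,
    format_pvalue,
    permutation_test_mean,
    permutation_test_per_species,
)


def _matrix_from_counts(counts, n_species):
    pres = np.zeros((len(counts), n_species), dtype=bool)
    for i, c in enumerate(counts):
        pres[i, :c] = True
    return OrthologMatrix(
        tuple(f"g{i}" for i in range(len(counts))),
        tuple(f"s{j}" for j in range(n_species)),
        pres,
    )


class TestMeanTest:
    def test_degenerate_population_both_tails_one(self):
        m = _matrix_from_counts([3, 3, 3, 3], 5)
        r = permutation_test_mean(m, GeneSet("s", ("g0", "g1")), n_resamples=100, seed=0)
        assert r.p_enrich == 1.0 and r.p_deplete == 1.0

    def test_exact_enumeration_oracle(self, staircase_matrix):
        # counts {0..5}, set = the two most-conserved genes: only 1 of the
        # C(6,2)=15 subsets reaches the observed sum
        r = permutation_test_mean(staircase_matrix, GeneSet("top", ("g4", "g5")), seed=0)
        assert r.exact
        assert r.p_enrich == pytest.approx(1 / 15)
        assert r.p_deplete == pytest.approx(1.0)

    def test_tails_are_closed_inequalities(self, staircase_matrix):
        r = permutation_test_mean(staircase_matrix, GeneSet("mid", ("g1", "g4")), seed=0)
        assert r.p_enrich + r.p_deplete >= 1.0

    def test_sampling_agrees_with_enumeration(self):
        # Monte-Carlo error bound: |p_hat - p| <= 4 sqrt(p(1-p)/R)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 8, size=14).tolist()
        m = _matrix_from_counts(counts, 8)
        gs = GeneSet("s", ("g0", "g3", "g7"))
        exact = permutation_test_mean(m, gs, seed=0)  # C(14,3)=364 -> exact
        assert exact.exact
        R = 20_000
        sampled = permutation_test_mean(m, gs, n_resamples=R, seed=5, exact_threshold=1)
        assert not sampled.exact
        for p_hat, p in ((sampled.p_enrich, exact.p_enrich), (sampled.p_deplete, exact.p_deplete)):
            assert abs(p_hat - p) <= 4 * math.sqrt(p * (1 - p) / R) + 1e-12

    def test_reproducible_with_seed(self):
        m = _matrix_from_counts(list(range(8)) * 4, 8)
        gs = GeneSet("s", tuple(f"g{i}" for i in range(5)))
        a = permutation_test_mean(m, gs, n_resamples=2000, seed=42, exact_threshold=1)
        b = permutation_test_mean(m, gs, n_resamples=2000, seed=42, exact_threshold=1)
        assert a == b

    def test_p_is_multiple_of_resolution(self):
        m = _matrix_from_counts(list(range(8)) * 4, 8)
        gs = GeneSet("s", tuple(f"g{i}" for i in range(5)))
        r = permutation_test_mean(m, gs, n_resamples=1000, seed=3, exact_threshold=1)
        assert (r.p_enrich * r.n_resamples) == int(round(r.p_enrich * r.n_resamples))

    def test_below_resolution_formatting(self):
        m = _matrix_from_counts([0] * 30 + [8] * 2, 8)
        gs = GeneSet("s", ("g30", "g31"))  # the only max-count pair
        r = permutation_test_mean(m, gs, n_resamples=50, seed=0, exact_threshold=1)
        if r.p_enrich == 0.0:
            assert r.below_resolution
            assert format_pvalue(r).startswith("<")

    def test_set_not_subset_rejected(self, staircase_matrix):
        with pytest.raises(ValidationError):
            permutation_test_mean(staircase_matrix, GeneSet("s", ("nope",)), seed=0)


class TestPerSpeciesTest:
    def test_whole_population_gives_p_one_everywhere(self, staircase_matrix):
        gs = GeneSet("all", staircase_matrix.genes)
        results = permutation_test_per_species(staircase_matrix, gs, n_resamples=50, seed=0)
        assert all(r.p_enrich == 1.0 and r.p_deplete == 1.0 for r in results)

    def test_exhaustive_two_species_oracle(self):
        # 2 species, 4 genes; enumerate all C(4,2)=6 subsets by hand
        pres = np.array([[1, 0], [1, 1], [0, 1], [0, 0]], dtype=bool)
        m = OrthologMatrix(("g0", "g1", "g2", "g3"), ("s0", "s1"), pres)
        gs = GeneSet("s", ("g0", "g1"))  # observed totals: s0=2, s1=1
        results = permutation_test_per_species(m, gs, seed=0)
        assert results[0].exact
        # s0 totals over subsets {01,02,03,12,13,23}: 2,1,1,1,1,0
        assert results[0].p_enrich == pytest.approx(1 / 6)
        assert results[0].p_deplete == pytest.approx(1.0)
        # s1 totals: 1,1,0,2,1,1 ; observed 1
        assert results[1].p_enrich == pytest.approx(5 / 6)
        assert results[1].p_deplete == pytest.approx(5 / 6)

    def test_shared_draws_match_mean_test_seed(self):
        # one resampling pass scores all species: per-species results share R and seed
        m = _matrix_from_counts(list(range(6)) * 5, 8)
        gs = GeneSet("s", tuple(f"g{i}" for i in range(4)))
        results = permutation_test_per_species(m, gs, n_resamples=500, seed=9, exact_threshold=1)
        assert {r.seed for r in results} == {9}
        assert {r.n_resamples for r in results} == {500}


class TestNullCalibration:
    def test_uniform_pvalues_under_null(self):
        # beta = 0 sets on a modest population: p_enrich approximately U(0,1)
        from orthoconserve.synthetic_data import SyntheticConfig, generate_gene_sets, generate_ortholog_matrix
        from scipy import stats

        cfg = SyntheticConfig(n_genes=600, seed=21, set_sizes=(40,))
        m = generate_ortholog_matrix(cfg)
        pvals = []
        for s in range(120):
            gs = generate_gene_sets(m, [40], 0.0, seed=1000 + s)[0]
            r = permutation_test_mean(m, gs, n_resamples=500, seed=s, exact_threshold=1)
            pvals.append(r.p_enrich)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monotone_power_in_beta(self):
        from orthoconserve.synthetic_data import SyntheticConfig, generate_gene_sets, generate_ortholog_matrix

        cfg = SyntheticConfig(n_genes=600, seed=22, set_sizes=(40,))
        m = generate_ortholog_matrix(cfg)
        med = {}
        for beta in (0.0, 0.25, 0.5):
            ps = []
            for s in range(40):
                gs = generate_gene_sets(m, [40], beta, seed=2000 + s)[0]
                ps.append(permutation_test_mean(m, gs, 400, seed=s, exact_threshold=1).p_enrich)
            med[beta] = np.median(ps)
        assert med[0.5] <= med[0.25] <= med[0.0]


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_textbook_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_constant_vector_identity(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_hand_step_up_formula(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        adj = bh_adjust(p)
        # independent oracle: sort ascending, adj(i) = min_{j>=i} p(j) m / j
        order = np.argsort(p)
        m = p.size
        stair = p[order] * m / np.arange(1, m + 1)
        expect = np.minimum.accumulate(stair[::-1])[::-1].clip(max=1.0)
        assert np.allclose(adj[order], expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
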