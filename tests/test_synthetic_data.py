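"""Generator tests: planted structure must be recoverable and reproducible."""

import numpy as np
import pytest

from orthoconserve.datatypes import ValidationError
from orthoconserve.synthetic_data import (
    SyntheticConfig,
    exact_enumeration_mean,
    expected_class_means,
    gene_classes,
    generate_annotation,
    generate_gene_sets,
    generate_ortholog_matrix,
    generate_species_panel,
)
from orthoconserve.annotation_enrichment import term_overrepresentation


class TestSpeciesPanel:
    def test_study_shaped_panel(self):
        panel = generate_species_panel([("arthropoda", 17), ("eutheria", 10), ("other", 27)])
        assert len(panel.species) == 54
        assert len(panel.clade_members("eutheria")) == 10
        assert panel.reference_species not in panel.species

    def test_minimal_panel(self):
        panel = generate_species_panel([("solo", 1)])
        assert panel.species == ("solo_01",)

    def test_determinism(self):
        spec = [("a", 3), ("b", 2)]
        assert generate_species_panel(spec) == generate_species_panel(spec)

    def test_duplicate_clade_rejected(self):
        with pytest.raises(ValidationError):
            generate_species_panel([("a", 2), ("a", 3)])


class TestOrthologMatrix:
    def test_degenerate_unique_class_gives_zero_counts(self):
        cfg = SyntheticConfig(n_genes=50, class_fractions=(1.0, 0.0, 0.0), set_sizes=(5,))
        m = generate_ortholog_matrix(cfg)
        assert m.counts().sum() == 0

    def test_determinism_bitwise(self):
        cfg = SyntheticConfig(n_genes=200, seed=7, set_sizes=(10,))
        a = generate_ortholog_matrix(cfg)
        b = generate_ortholog_matrix(cfg)
        assert a.genes == b.genes
        assert np.array_equal(a.presence, b.presence)

    def test_class_means_match_binomial_oracle(self):
        # empirical mean count per conservation class vs Sigma_s p_s within 3 SE
        cfg = SyntheticConfig(seed=11)  # default study-sized population
        m = generate_ortholog_matrix(cfg)
        classes = gene_classes(cfg)
        counts = m.counts()
        expected = expected_class_means(cfg)
        panel = generate_species_panel(cfg.clade_spec)
        from orthoconserve.synthetic_data import _species_prob_matrix

        probs = _species_prob_matrix(cfg, panel)
        var = (probs * (1 - probs)).sum(axis=1)  # per-gene count variance by class
        for c in range(3):
            sel = classes == c
            n_c = sel.sum()
            assert n_c > 30
            se = np.sqrt(var[c] / n_c) if var[c] > 0 else 0.0
            assert abs(counts[sel].mean() - expected[c]) <= max(3 * se, 1e-12)

    def test_trimodal_histogram(self):
        cfg = SyntheticConfig(seed=5)
        m = generate_ortholog_matrix(cfg)
        hist = np.bincount(m.counts(), minlength=m.n_species + 1)
        # local maxima of the raw histogram, ignoring tiny bins
        floor = 0.005 * hist.sum()
        maxima = [
            k
            for k in range(len(hist))
            if hist[k] >= floor
            and hist[k] >= (hist[k - 1] if k > 0 else 0)
            and hist[k] >= (hist[k + 1] if k < len(hist) - 1 else 0)
        ]
        targets = [0, 15, 50]
        for t in targets:
            assert any(abs(k - t) <= 3 for k in maxima), (t, maxima)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_genes=0, set_sizes=())


class TestGeneSets:
    def test_beta_zero_is_unbiased(self):
        cfg = SyntheticConfig(n_genes=500, seed=3, set_sizes=(50,))
        m = generate_ortholog_matrix(cfg)
        pop_mean = m.counts().mean()
        means = []
        for s in range(200):
            gs = generate_gene_sets(m, [50], 0.0, seed=s)[0]
            means.append(np.mean([m.count_of(g) for g in gs.genes]))
        # mean of uniform draws matches the population mean
        assert abs(np.mean(means) - pop_mean) < 1.0

    def test_positive_beta_enriches(self):
        cfg = SyntheticConfig(n_genes=500, seed=3, set_sizes=(50,))
        m = generate_ortholog_matrix(cfg)
        gs = generate_gene_sets(m, [100], 0.5, seed=1)[0]
        set_mean = np.mean([m.count_of(g) for g in gs.genes])
        assert set_mean > m.counts().mean()

    def test_weighted_sampling_matches_enumeration_oracle(self):
        # 10-gene population, draws of size 2: empirical mean count of the
        # sampled sets must match the exhaustively enumerated Plackett-Luce
        # expectation
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=10)
        presence = np.zeros((10, 5), dtype=bool)
        for i, c in enumerate(counts):
            presence[i, :c] = True
        from orthoconserve.datatypes import OrthologMatrix

        m = OrthologMatrix(
            tuple(f"g{i}" for i in range(10)), tuple(f"s{j}" for j in range(5)), presence
        )
        beta = 0.5
        expected = exact_enumeration_mean(counts, 2, beta)
        draws = [
            np.mean([m.count_of(g) for g in generate_gene_sets(m, [2], beta, seed=s)[0].genes])
            for s in range(4000)
        ]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected) < 4 * se

    def test_extreme_beta_selects_max_count_gene(self):
        cfg = SyntheticConfig(n_genes=40, seed=9, set_sizes=(1,))
        m = generate_ortholog_matrix(cfg)
        counts = m.counts()
        if (counts == counts.max()).sum() != 1:  # ensure a unique maximum
            counts[0] = counts.max() + 1
            presence = m.presence.copy()
            presence[0] = True
            from orthoconserve.datatypes import OrthologMatrix

            m = OrthologMatrix(m.genes, m.species, presence)
            counts = m.counts()
        best = m.genes[int(np.argmax(counts))]
        gs = generate_gene_sets(m, [1], 50.0, seed=4)[0]
        assert gs.genes == (best,)

    def test_oversized_set_rejected(self):
        cfg = SyntheticConfig(n_genes=20, seed=1, set_sizes=(5,))
        m = generate_ortholog_matrix(cfg)
        with pytest.raises(ValidationError):
            generate_gene_sets(m, [21], 0.0, seed=0)

    def test_directions_assigned(self):
        cfg = SyntheticConfig(n_genes=50, seed=2, set_sizes=(10,))
        m = generate_ortholog_matrix(cfg)
        gs = generate_gene_sets(m, [10], 0.0, seed=0)[0]
        assert set(gs.direction_of) == set(gs.genes)
        assert set(gs.direction_of.values()) <= {"up", "down"}


class TestAnnotation:
    def test_planted_term_attains_minimal_p(self):
        genes = [f"g{i}" for i in range(100)]
        study = genes[:10]
        term_map, _ = generate_annotation(
            genes, n_terms=20, planted_terms={"planted": study}, seed=0
        )
        results = term_overrepresentation(study, genes, term_map, background="all")
        by_term = {r.term: r for r in results}
        planted = by_term["planted"]
        assert planted.k == planted.K == len(study)
        assert planted.p_raw == min(r.p_raw for r in results)

    def test_chain_ancestor_closure(self):
        from orthoconserve.annotation_enrichment import ancestor_closure, TermEnrichmentResult

        edges = [("c", "b"), ("b", "a")]
        enriched = [TermEnrichmentResult("c", 2, 2, 5, 10, 0.01, 0.02)]
        rows = ancestor_closure(enriched, edges)
        assert {r.term for r in rows} == {"a", "b", "c"}
        sig = {r.term: r.significance for r in rows}
        assert sig["a"] == sig["b"] == "parent-only"

    def test_cycle_rejected(self):
        genes = [f"g{i}" for i in range(20)]
        with pytest.raises(ValidationError):
            generate_annotation(genes, 3, seed=0, parent_edges=[("a", "b"), ("b", "a")])

    def test_reproducibility(self):
        genes = [f"g{i}" for i in range(50)]
        a = generate_annotation(genes, 10, seed=4)
        b = generate_annotation(genes, 10, seed=4)
        assert a == b
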