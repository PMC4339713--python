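import numpy as np
import pandas as pd
import pytest

from conftest import make_universe
from helpers import brute_force_pvalue, mc_standard_error, random_tiny_instance
from osseoprofile import synthetic_data
from osseoprofile.go_enrichment import (
    EnrichmentConfig,
    _poisson_binomial_sf,
    assign_length_bins,
    enrich,
    exact_pvalue,
    permutation_pvalue,
    sample_control_set,
    significance_threshold,
    term_fraction,
)


class TestLengthBins:
    def test_even_split_distinct_lengths(self):
        lengths = {f"g{i}": 100 * (i + 1) for i in range(10)}
        bins = assign_length_bins(make_universe(lengths), 2)
        short = {g for g, length in lengths.items() if length <= 500}
        assert set(bins.index[bins == 0]) == short
        assert (bins == 1).sum() == 5

    def test_identical_lengths_collapse_to_one_bin(self):
        bins = assign_length_bins(make_universe({f"g{i}": 777 for i in range(8)}), 4)
        assert bins.nunique() == 1

    def test_quantile_occupancy(self, rng):
        lengths = {f"g{i:04d}": int(v) for i, v in
                   enumerate(np.exp(rng.normal(8, 1, 1000)))}
        bins = assign_length_bins(make_universe(lengths), 10)
        counts = bins.value_counts()
        assert len(counts) == 10
        assert counts.min() >= 99 and counts.max() <= 101
        # bins are ordered by length: every gene in bin b is shorter than
        # every gene in bin b+2 (ties can only straddle adjacent bins)
        series = pd.Series(lengths)
        assert series[bins == 0].max() <= series[bins == 9].min()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            assign_length_bins(make_universe({}), 2)


class TestControlSampling:
    def test_singleton_bin_forces_self(self, rng):
        # one huge gene alone in the top bin must draw itself
        lengths = {"g0": 100, "g1": 110, "g2": 120, "whale": 1_000_000}
        u = make_universe(lengths)
        bins = assign_length_bins(u, 4)
        assert (bins == bins.loc["whale"]).sum() == 1
        for _ in range(5):
            assert sample_control_set(["whale"], bins, rng) == ["whale"]

    def test_size_contract(self, rng):
        u = make_universe({f"g{i}": 100 + i for i in range(20)})
        bins = assign_length_bins(u, 4)
        for size in (1, 5, 20):
            control = sample_control_set([f"g{i}" for i in range(size)], bins, rng)
            assert len(control) == size

    def test_unknown_test_gene_rejected(self, rng):
        u = make_universe({"g0": 100})
        bins = assign_length_bins(u, 1)
        with pytest.raises(ValueError):
            sample_control_set(["nope"], bins, rng)

    def test_uniform_within_bin(self, rng):
        # one test gene in a 4-gene bin: each member drawn ~U(1/4) over 10,000 draws
        u = make_universe({f"g{i}": 500 for i in range(4)})
        bins = assign_length_bins(u, 1)
        draws = [sample_control_set(["g0"], bins, rng)[0] for _ in range(10_000)]
        freq = pd.Series(draws).value_counts(normalize=True)
        se3 = 3 * mc_standard_error(0.25, 10_000)
        for g in u.gene_ids:
            assert freq.get(g, 0.0) == pytest.approx(0.25, abs=se3 + 1e-9)


class TestTermFraction:
    def test_fractions(self):
        u = make_universe({f"g{i}": 100 for i in range(4)},
                          {"GO:0000001": ["g0", "g1"], "GO:0000002": ["g3"]})
        assert term_fraction(["g2", "g3"], "GO:0000001", u) == 0.0
        assert term_fraction(["g0", "g1"], "GO:0000001", u) == 1.0
        assert term_fraction(["g0", "g1", "g2", "g3"], "GO:0000001", u) == 0.5
        # multiset members count with multiplicity
        assert term_fraction(["g0", "g0", "g2", "g3"], "GO:0000001", u) == 0.5
        with pytest.raises(ValueError):
            term_fraction([], "GO:0000001", u)


class TestPermutationPvalue:
    def test_zero_f_test_gives_p_one(self, rng):
        u = make_universe({f"g{i}": 100 * (i + 1) for i in range(6)},
                          {"GO:0000001": ["g5"]})
        p = permutation_pvalue(["g0", "g1"], "GO:0000001", u,
                               EnrichmentConfig(n_draws=200, n_length_bins=1), rng)
        assert p == 1.0

    def test_term_private_to_test_set_gives_p_zero(self, rng):
        # term carried only by the test genes; bins contain many non-carriers
        lengths = {f"g{i}": 100 for i in range(40)}
        u = make_universe(lengths, {"GO:0000001": ["g0", "g1"]})
        p = permutation_pvalue(["g0", "g1"], "GO:0000001", u,
                               EnrichmentConfig(n_draws=300, n_length_bins=1), rng)
        assert p < 0.05  # both carriers redrawn together is a (1/20)^2 event

    def test_agrees_with_exact_oracle_on_tiny_instances(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(20):
            universe, test = random_tiny_instance(rng)
            bins = assign_length_bins(universe, 2)
            for term in universe.term_universe:
                p_exact = exact_pvalue(test, term, universe, bins)
                p_mc = permutation_pvalue(
                    test, term, universe,
                    EnrichmentConfig(n_draws=2_000, n_length_bins=2),
                    np.random.default_rng(checked),
                )
                tol = 3 * mc_standard_error(p_exact, 2_000) + 1e-12
                assert abs(p_mc - p_exact) <= tol
                checked += 1
        assert checked >= 20


class TestExactPvalue:
    def test_single_bernoulli(self):
        # one test gene carrying the term, alone responsible: p = bin prevalence
        u = make_universe({f"g{i}": 100 for i in range(4)}, {"GO:0000001": ["g0"]})
        bins = assign_length_bins(u, 1)
        assert exact_pvalue(["g0"], "GO:0000001", u, bins) == pytest.approx(0.25)

    def test_two_independent_halves(self):
        u = make_universe({f"g{i}": 100 for i in range(4)},
                          {"GO:0000001": ["g0", "g1"]})
        bins = assign_length_bins(u, 1)
        assert exact_pvalue(["g0", "g1"], "GO:0000001", u, bins) == pytest.approx(0.25)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            universe, test = random_tiny_instance(rng)
            bins = assign_length_bins(universe, int(rng.integers(1, 3)))
            for term in universe.term_universe:
                assert exact_pvalue(test, term, universe, bins) == pytest.approx(
                    brute_force_pvalue(test, term, universe, bins), abs=1e-12
                )

    def test_sf_monotone_in_count(self, rng):
        probs = rng.uniform(0.05, 0.9, size=6)
        values = [_poisson_binomial_sf(probs, k) for k in range(8)]
        assert values[0] == 1.0
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)


class TestEnrich:
    def _universe(self, n=30):
        lengths = {f"g{i:02d}": 100 * (i + 1) for i in range(n)}
        terms = {
            "GO:0000001": [f"g{i:02d}" for i in range(0, 6)],
            "GO:0000002": [f"g{i:02d}" for i in range(10, 25)],
        }
        return make_universe(lengths, terms, domains={"GO:0000002": "molecular_function"})

    def test_threshold_is_reciprocal_term_count(self):
        assert significance_threshold(self._universe()) == pytest.approx(0.5)

    def test_unannotated_test_set_all_p_one(self):
        u = self._universe()
        results = enrich(["g26", "g27", "g28"], u, EnrichmentConfig(n_draws=100, seed=0))
        assert {r.p_value for r in results} == {1.0}
        assert not any(r.significant for r in results)

    def test_result_invariants_and_sorting(self):
        u = self._universe()
        results = enrich([f"g{i:02d}" for i in range(6)], u,
                         EnrichmentConfig(n_draws=500, n_length_bins=3, seed=1))
        assert len(results) == 2
        for r in results:
            assert 0.0 <= r.p_value <= 1.0
            assert r.f_test == pytest.approx(r.n_test_with_term / 6)
            assert r.significant == (r.p_value < 0.5)
        assert [r.domain for r in results] == sorted(r.domain for r in results)

    def test_determinism_under_seed(self):
        u = self._universe()
        cfg = EnrichmentConfig(n_draws=400, n_length_bins=3, seed=77)
        a = enrich([f"g{i:02d}" for i in range(8)], u, cfg)
        b = enrich([f"g{i:02d}" for i in range(8)], u, cfg)
        assert a == b

    def test_empty_term_universe_warns(self):
        u = make_universe({"g0": 100, "g1": 200})
        with pytest.warns(UserWarning, match="empty"):
            assert enrich(["g0"], u, EnrichmentConfig(n_draws=10)) == []

    def test_planted_term_detected(self):
        cfg = synthetic_data.SyntheticConfig(
            n_genes=400, n_terms=50, prevalence_low=0.03, prevalence_high=0.08,
            zero_fraction=0.0, n_up_1w=50, n_down_1w=20, n_up_4w=30, n_down_4w=20,
            overlap_up=10, overlap_down=5, expression_sigma=0.0,
            n_enriched_terms=2, enrichment_multiplier=10.0, seed=13,
        )
        rng = cfg.rng()
        u = synthetic_data.generate_universe(cfg, rng)
        _, ledger = synthetic_data.generate_expression(u, cfg, rng)
        results = enrich(sorted(ledger.up["1w"]), u,
                         EnrichmentConfig(n_draws=1_000, seed=5))
        by_term = {r.term: r for r in results}
        for term in ledger.enriched_terms:
            assert by_term[term].significant
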