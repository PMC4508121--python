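import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from flocknet import (
    CategoricalModel,
    binomial_tail,
    cooccurrence_count,
    cooccurrence_prob_categorical,
    cooccurrence_prob_series_markov,
    critical_value,
    fit_categorical,
    fit_markov,
    poisson_binomial_pmf,
    results_to_frame,
    test_all_pairs,
    test_pair,
)
from flocknet.affiliation_test import tail_probabilities
from conftest import make_occ


def enumerate_pmf(ps):
    """Exhaustive 2^H enumeration of the success-count distribution."""
    ps = np.asarray(ps, dtype=float)
    H = ps.size
    bits = (np.arange(1 << H)[:, None] >> np.arange(H)) & 1
    probs = np.prod(np.where(bits == 1, ps, 1 - ps), axis=1)
    return np.bincount(bits.sum(axis=1), weights=probs, minlength=H + 1)


class TestCounts:
    def test_identical_sequences_maximal(self, occ_pair_identical):
        assert cooccurrence_count(occ_pair_identical, 0, 1) == 7

    def test_disjoint_sequences_zero(self):
        occ = make_occ([[0, 0, 0], [1, 2, 1]], 3)
        assert cooccurrence_count(occ, 0, 1) == 0

    def test_partial_overlap(self):
        occ = make_occ([[0, 1, 2, 0], [0, 2, 2, 1]], 3)
        assert cooccurrence_count(occ, 0, 1) == 2

    def test_self_pair_rejected(self, occ_pair_identical):
        with pytest.raises(ValueError):
            cooccurrence_count(occ_pair_identical, 1, 1)


class TestCooccurrenceProbability:
    def test_uniform(self):
        u = CategoricalModel(np.full(3, 1 / 3))
        assert cooccurrence_prob_categorical(u, u) == pytest.approx(1 / 3)

    def test_disjoint_support(self):
        a = CategoricalModel(np.array([1.0, 0.0, 0.0]))
        b = CategoricalModel(np.array([0.0, 1.0, 0.0]))
        assert cooccurrence_prob_categorical(a, b) == 0.0

    def test_hotspot(self):
        h = CategoricalModel(np.array([0.25, 0.25, 0.5]))
        assert cooccurrence_prob_categorical(h, h) == pytest.approx(0.375)

    def test_dimension_mismatch(self):
        a = CategoricalModel(np.array([0.5, 0.5]))
        b = CategoricalModel(np.array([1 / 3] * 3))
        with pytest.raises(ValueError):
            cooccurrence_prob_categorical(a, b)


class TestBinomialTail:
    @pytest.mark.parametrize(
        "H,p,e,expected",
        [
            (7, 0.3, 0, 1.0),
            (5, 0.0, 1, 0.0),
            (10, 1 / 3, 8, 201 / 59049),
        ],
    )
    def test_values(self, H, p, e, expected):
        assert binomial_tail(H, p, e) == pytest.approx(expected, rel=1e-12)


class TestPoissonBinomial:
    def test_two_trial_enumeration(self):
        np.testing.assert_allclose(
            poisson_binomial_pmf([0.5, 0.25]), [0.375, 0.5, 0.125]
        )

    def test_constant_p_equals_binomial(self):
        H, p = 50, 0.21
        np.testing.assert_allclose(
            poisson_binomial_pmf(np.full(H, p)),
            stats.binom.pmf(np.arange(H + 1), H, p),
            atol=1e-12,
        )

    def test_all_ones_point_mass(self):
        pmf = poisson_binomial_pmf(np.ones(6))
        np.testing.assert_allclose(pmf, np.eye(7)[6])

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=10)
    )
    def test_matches_exhaustive_enumeration(self, ps):
        np.testing.assert_allclose(
            poisson_binomial_pmf(ps), enumerate_pmf(ps), atol=1e-12
        )

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=1, max_size=30)
    )
    def test_conservation_and_monotone_tail(self, ps):
        pmf = poisson_binomial_pmf(ps)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        tails = tail_probabilities(pmf)
        assert np.all(np.diff(tails) <= 1e-15)


class TestMarkovSeries:
    def test_identical_point_masses(self):
        m = fit_markov(make_occ([[0, 1, 0, 1, 0]], 2), 0)
        ps = cooccurrence_prob_series_markov(m, m, 4)
        np.testing.assert_allclose(ps, 1.0)

    def test_antiphase_periodic_chains(self):
        a = fit_markov(make_occ([[0, 1, 0, 1, 0]], 2), 0)
        b = fit_markov(make_occ([[1, 0, 1, 0, 1]], 2), 0)
        ps = cooccurrence_prob_series_markov(a, b, 5)
        np.testing.assert_allclose(ps, 0.0)

    def test_categorical_series_is_constant(self):
        occ = make_occ([[0, 1, 2, 0], [2, 1, 0, 0]], 3)
        pis = [fit_categorical(occ, n) for n in range(2)]
        r = test_pair(occ, pis, 0, 1, alpha=0.05, model_kind="categorical")
        assert np.unique(r.p_series).size == 1
        assert r.p_series[0] == pytest.approx(
            cooccurrence_prob_categorical(pis[0], pis[1])
        )


class TestCriticalValue:
    def test_binomial_worked_case(self):
        assert critical_value((10, 1 / 3), 0.05) == 6

    def test_accepts_pmf(self):
        pmf = poisson_binomial_pmf(np.full(10, 1 / 3))
        assert critical_value(pmf, 0.05) == 6

    def test_alpha_near_one(self):
        beta = critical_value((10, 0.5), 0.9999)
        assert beta == 0  # only P(E >= 0) = 1 exceeds alpha

    def test_alpha_out_of_range(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                critical_value((10, 0.5), bad)

    def test_rejection_rule_equivalence(self):
        """(e > beta) <=> (tail(e) <= alpha) over random binomial nulls."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            H = int(rng.integers(1, 21))
            p = float(rng.uniform(0.01, 0.99))
            alpha = float(rng.uniform(0.001, 0.5))
            beta = critical_value((H, p), alpha)
            for e in range(H + 1):
                assert (e > beta) == (binomial_tail(H, p, e) <= alpha)


class TestPairTest:
    def test_identical_trajectories_reject(self, occ_pair_identical):
        models = [fit_categorical(occ_pair_identical, n) for n in range(2)]
        r = test_pair(occ_pair_identical, models, 0, 1, alpha=0.05)
        assert r.e_obs == 7 and r.reject
        assert r.p_value <= 0.05

    def test_single_cell_partition_never_rejects(self):
        occ = make_occ([[0] * 10, [0] * 10], 1)
        models = [fit_categorical(occ, n) for n in range(2)]
        r = test_pair(occ, models, 0, 1, alpha=0.05)
        assert r.e_obs == 10
        np.testing.assert_allclose(r.p_series, 1.0)
        assert r.p_value == 1.0 and not r.reject

    def test_reject_iff_pvalue_below_alpha(self):
        rng = np.random.default_rng(5)
        occ = make_occ([rng.integers(0, 4, 60), rng.integers(0, 4, 60)], 4)
        for alpha in (0.05, 0.3, 0.9):
            models = [fit_categorical(occ, n) for n in range(2)]
            r = test_pair(occ, models, 0, 1, alpha=alpha)
            assert r.reject == (r.p_value <= alpha)

    def test_markov_kind_runs_pooled(self):
        rng = np.random.default_rng(9)
        occ = make_occ(
            [rng.integers(0, 3, 200), rng.integers(0, 3, 200)], 3
        )
        model = fit_markov(occ, "pooled")
        r = test_pair(occ, model, 0, 1, alpha=0.05, model_kind="markov")
        assert r.p_series.shape == (200,)
        assert 0.0 <= r.p_value <= 1.0

    def test_all_pairs_table(self):
        rng = np.random.default_rng(2)
        occ = make_occ([rng.integers(0, 3, 50) for _ in range(4)], 3)
        results = test_all_pairs(occ, fit_categorical(occ, "pooled"), 0.05)
        assert len(results) == 6
        df = results_to_frame(results)
        assert set(df.columns) >= {"e_obs", "p_value", "beta", "reject"}
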