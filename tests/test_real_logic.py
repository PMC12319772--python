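"""The fuzzy-logic algebra: pMeanError, quantifier, SatAgg, satisfaction loss."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nesyqsar.nn import MLP, NetworkSpec
from nesyqsar.real_logic import (
    Axiom,
    DeviationOrder,
    GroundedPredicate,
    KnowledgeBase,
    TruthDegree,
    pmean_error,
    pmean_error_grad,
    predicate_truth,
    quantify_forall,
    sat_agg,
    satisfaction_loss,
)

truth_vectors = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30)
orders = st.floats(1.0, 50.0)


class TestTruthTypes:
    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_truth_degree_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            TruthDegree(bad)

    def test_deviation_order_requires_p_at_least_one(self):
        with pytest.raises(ValueError):
            DeviationOrder(0.5)
        assert float(DeviationOrder(1.0)) == 1.0


class TestPMeanError:
    # expected values from direct arithmetic evaluation of the definition
    @pytest.mark.parametrize(
        "truths, p, expected",
        [
            ([1, 1, 1], 2, 1.0),                       # zero deviation
            ([0], 2, 0.0),                             # maximal deviation
            ([0.8, 0.6], 2, 1 - np.sqrt((0.2**2 + 0.4**2) / 2)),
            ([0.2, 0.4, 0.6], 1, 0.4),                 # p=1 is the arithmetic mean
        ],
    )
    def test_analytic_cases(self, truths, p, expected):
        assert pmean_error(truths, p) == pytest.approx(expected, abs=1e-9)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            pmean_error([], 2)
        with pytest.raises(ValueError):
            pmean_error([0.5, 1.2], 2)

    @given(d=st.floats(0.0, 1.0), p=orders, n=st.integers(1, 20))
    def test_constant_deviation_identity(self, d, p, n):
        """All u_i = 1−d gives exactly 1−d for every p (generalized-mean fixed point)."""
        assert pmean_error([1.0 - d] * n, p) == pytest.approx(1.0 - d, abs=1e-9)

    @given(u=truth_vectors, p=orders)
    def test_output_in_unit_interval(self, u, p):
        assert 0.0 <= pmean_error(u, p) <= 1.0

    def test_monotone_non_increasing_in_p(self, rng):
        for _ in range(100):
            u = rng.random(rng.integers(1, 20))
            ps = [1.0, 1.5, 2.0, 4.0, 8.0, 32.0]
            vals = [pmean_error(u, p) for p in ps]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_large_p_approaches_min(self, rng):
        # the gap to min scales as log(n)/p, so p=200 guarantees 1e-2 only
        # for short vectors; longer ones get the rate-aware bound
        for _ in range(100):
            u = rng.random(rng.integers(2, 20))
            bound = max(1e-2, np.log(u.size) / 200.0 + 1e-3)
            assert pmean_error(u, 200.0) == pytest.approx(u.min(), abs=bound)
            assert pmean_error(u[:5], 200.0) == pytest.approx(u[:5].min(), abs=1e-2)

    def test_monotone_in_truths(self, rng):
        for _ in range(100):
            u = rng.random(8)
            i = int(rng.integers(8))
            bumped = u.copy()
            bumped[i] = min(1.0, bumped[i] + rng.random() * (1 - bumped[i]))
            assert pmean_error(bumped, 2.0) >= pmean_error(u, 2.0) - 1e-12

    def test_gradient_is_nonnegative_and_matches_finite_difference(self, rng):
        u = rng.uniform(0.05, 0.95, size=7)
        for p in (1.0, 2.0, 5.0):
            g = pmean_error_grad(u, p)
            assert np.all(g >= 0.0)
            h = 1e-7
            for i in range(u.size):
                up, um = u.copy(), u.copy()
                up[i] += h
                um[i] -= h
                num = (pmean_error(up, p) - pmean_error(um, p)) / (2 * h)
                assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestQuantifier:
    def test_perfect_classification_is_fully_true(self):
        assert quantify_forall([1.0, 1.0, 1.0, 1.0], 2) == 1.0

    @given(u=st.floats(0.0, 1.0), p=orders)
    def test_singleton_domain_collapses_to_element(self, u, p):
        assert quantify_forall([u], p) == pytest.approx(u, abs=1e-9)

    def test_arithmetic_oracle(self):
        expected = 1 - np.sqrt((0.01 + 0.01 + 0.81) / 3)
        assert quantify_forall([0.9, 0.9, 0.1], 2) == pytest.approx(expected, abs=1e-9)


class TestGroundedPredicate:
    def test_uniform_output_for_zeroed_final_layer(self, tiny_predicate, rng):
        net = tiny_predicate.network
        net.weights[-1][...] = 0.0
        net.biases[-1][...] = 0.0
        x = rng.normal(size=4)
        assert float(predicate_truth(tiny_predicate, x, 0)) == pytest.approx(0.5)
        assert float(predicate_truth(tiny_predicate, x, 1)) == pytest.approx(0.5)

    def test_per_class_truths_sum_to_one(self, tiny_predicate, rng):
        x = rng.normal(size=(20, 4))
        t0 = tiny_predicate.truths(x, np.zeros(20, dtype=int))
        t1 = tiny_predicate.truths(x, np.ones(20, dtype=int))
        np.testing.assert_allclose(t0 + t1, 1.0, atol=1e-12)

    def test_dimension_and_label_validation(self, tiny_predicate, rng):
        with pytest.raises(ValueError):
            tiny_predicate.truths(rng.normal(size=(3, 5)), np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            tiny_predicate.truths(rng.normal(size=(3, 4)), np.full(3, 2))


class TestSatAggAndLoss:
    def test_single_axiom_kb_equals_quantified_truth(self, tiny_predicate, rng):
        kb = KnowledgeBase(axioms=[Axiom("only", class_value=0, label=0)])
        x = rng.normal(size=(10, 4))
        y = np.zeros(10, dtype=int)
        u = tiny_predicate.truths(x, y)
        assert sat_agg(kb, tiny_predicate, x, y) == pytest.approx(pmean_error(u, 2.0), abs=1e-12)

    def test_fully_satisfied_axioms_give_one_and_zero_loss(self, tiny_predicate, rng):
        # saturate the network so it outputs ~one-hot for class 0
        net = tiny_predicate.network
        net.weights[-1][...] = 0.0
        net.biases[-1][...] = np.array([50.0, -50.0])
        kb = KnowledgeBase(axioms=[Axiom("a", 0, 0)])
        x = rng.normal(size=(6, 4))
        y = np.zeros(6, dtype=int)
        assert sat_agg(kb, tiny_predicate, x, y) == pytest.approx(1.0, abs=1e-9)
        assert satisfaction_loss(kb, tiny_predicate, x, y) == pytest.approx(0.0, abs=1e-9)

    def test_cross_axiom_aggregation_matches_pmean_oracle(self):
        # axiom truths [0.8, 0.6] at p=2 must aggregate like pmean_error
        expected = 1 - np.sqrt((0.2**2 + 0.4**2) / 2)
        assert pmean_error([0.8, 0.6], 2) == pytest.approx(expected, abs=1e-9)

    def test_loss_satagg_complement_identity(self, tiny_predicate, rng):
        kb = KnowledgeBase.binary_classification()
        for _ in range(10):
            x = rng.normal(size=(16, 4))
            y = rng.integers(0, 2, size=16)
            if np.unique(y).size < 2:
                continue
            s = sat_agg(kb, tiny_predicate, x, y)
            loss = satisfaction_loss(kb, tiny_predicate, x, y)
            assert loss + s == pytest.approx(1.0, abs=1e-12)

    def test_batch_without_any_axiom_class_errors(self, tiny_predicate, rng):
        kb = KnowledgeBase(axioms=[Axiom("a", 5, 0)])
        with pytest.raises(ValueError):
            sat_agg(kb, tiny_predicate, rng.normal(size=(4, 4)), np.zeros(4, dtype=int))

    def test_missing_class_axiom_is_skipped(self, tiny_predicate, rng):
        kb = KnowledgeBase.binary_classification()
        x = rng.normal(size=(5, 4))
        y = np.zeros(5, dtype=int)  # no inactive members in this batch
        u = tiny_predicate.truths(x, y)
        assert sat_agg(kb, tiny_predicate, x, y) == pytest.approx(pmean_error(u, 2.0), abs=1e-12)

    def test_empty_kb_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeBase(axioms=[])

    @pytest.mark.parametrize("operator, expected", [("min", 0.6), ("mean", 0.7)])
    def test_alternative_satagg_operators(self, tiny_predicate, operator, expected, monkeypatch):
        from nesyqsar import real_logic

        kb = KnowledgeBase.binary_classification(satagg_operator=operator)
        monkeypatch.setattr(
            real_logic, "_axiom_truths", lambda *a, **k: ([0.8, 0.6], [None, None])
        )
        assert sat_agg(kb, tiny_predicate, np.zeros((2, 4)), np.array([0, 1])) == pytest.approx(
            expected
        )
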