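import pytest

from pcombine import (
    BoundUnavailableError,
    ExpansionConfig,
    InputDomainError,
    WeightedPValueSet,
    cluster_inverse_weights,
    cluster_moments,
    correction_terms,
    expansion_combine,
    fisher_combine,
    gc_combine,
    gc_parameters_from_set,
    good_combine,
    truncation_bound,
)
from pcombine.expansion import _evaluate, _pipeline
from pcombine.oracles import generate_fixture


def exact_reference(pset, digits=60):
    """Exact combined p-value from the unclustered grouped-rate formula."""
    return gc_combine(gc_parameters_from_set(pset), digits=digits).pvalue


class TestReductions:
    def test_zero_radius_recovers_exact_result(self, rng):
        p = [0.1, 0.2, 0.3]
        w = [1.0, 2.0, 3.0]
        s = WeightedPValueSet(p, w)
        e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.0))
        assert e.pvalue == pytest.approx(exact_reference(s), rel=1e-15)
        assert e.truncation_bound == 0.0

    def test_zero_radius_corrections_all_vanish(self):
        s = WeightedPValueSet([0.05, 0.4], [0.8, 1.7])
        cs, moments, t = _pipeline(s, 0.0, 4)
        terms = correction_terms(cs, moments, t, 4)
        assert terms and all(term.value == 0.0 for term in terms)

    def test_equal_weights_reduce_to_fisher(self):
        s = WeightedPValueSet([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])
        e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.05))
        f = fisher_combine(s)
        assert e.pvalue == pytest.approx(f.pvalue, rel=1e-13)

    def test_matches_good_on_distinct_well_separated_weights(self):
        s = WeightedPValueSet([0.02, 0.6, 0.31], [0.5, 1.0, 2.0])
        e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.0))
        g = good_combine(s, digits=50)
        assert e.pvalue == pytest.approx(g.pvalue, rel=1e-12)


class TestTermStructure:
    def test_max_order_zero_has_no_terms(self):
        s = WeightedPValueSet([0.1, 0.2], [1.0, 1.05])
        cs, moments, t = _pipeline(s, 0.1, 1)
        assert correction_terms(cs, moments, t, 0) == []

    def test_no_order_one_terms(self):
        cs = cluster_inverse_weights([0.94, 0.99, 1.07], 0.2)
        moments = cluster_moments(cs, 4)
        terms = correction_terms(cs, moments, 2.0, 4)
        assert terms and all(term.order != 1 for term in terms)
        assert all(term.order == sum(term.multiplicity_shift) for term in terms)

    def test_orders_two_three_touch_single_cluster(self):
        cs = cluster_inverse_weights([0.58, 0.62, 1.38, 1.42], 0.1)
        moments = cluster_moments(cs, 4)
        for term in correction_terms(cs, moments, 3.0, 4):
            if term.order in (2, 3):
                assert sum(1 for k in term.multiplicity_shift if k) == 1

    def test_order_four_includes_cross_cluster_mixing(self):
        cs = cluster_inverse_weights([0.58, 0.62, 1.38, 1.42], 0.1)
        moments = cluster_moments(cs, 4)
        shifts = {t.multiplicity_shift for t in correction_terms(cs, moments, 3.0, 4)}
        assert (2, 2) in shifts

    def test_order_coefficients_match_moment_formulas(self):
        # one cluster: g2 = D2/2, g3 = -D3/3, g4 = D4/4 + (D2/2)^2/2
        cs = cluster_inverse_weights([0.9, 1.0, 1.15], 0.5)
        moments = cluster_moments(cs, 4)
        D2, D3, D4 = (moments.D(0, k) for k in (2, 3, 4))
        by_shift = {
            t.multiplicity_shift: t.coefficient
            for t in correction_terms(cs, moments, 3.3, 4)
        }
        assert by_shift[(2,)] == pytest.approx(D2 / 2, rel=1e-13)
        assert by_shift[(3,)] == pytest.approx(-D3 / 3, rel=1e-13)
        assert by_shift[(4,)] == pytest.approx(D4 / 4 + (D2 / 2) ** 2 / 2, rel=1e-13)

    def test_symmetric_cluster_order_three_term_is_present_and_zero(self):
        # dyadic members: center and deviations exact, D3 identically zero
        cs = cluster_inverse_weights([0.75, 1.25], 0.75)
        moments = cluster_moments(cs, 3)
        assert moments.D(0, 3) == 0.0
        terms = correction_terms(cs, moments, 2.0, 3)
        order3 = [t for t in terms if t.order == 3]
        assert len(order3) == 1
        assert order3[0].coefficient == 0.0 and order3[0].value == 0.0

    def test_singleton_clusters_have_zero_terms(self):
        cs = cluster_inverse_weights([0.7, 1.3], 0.1)
        moments = cluster_moments(cs, 4)
        assert all(t.value == 0.0 for t in correction_terms(cs, moments, 2.0, 4))

    def test_unsupported_order_rejected(self):
        with pytest.raises(InputDomainError):
            ExpansionConfig(max_order=7)
        with pytest.raises(InputDomainError):
            ExpansionConfig(max_order=1)


class TestAccuracy:
    def test_stable_in_double_precision_on_nearly_equal_weights(self, nearly_equal_set):
        hp = good_combine(nearly_equal_set, digits=50).pvalue
        e = expansion_combine(
            nearly_equal_set, ExpansionConfig(max_order=4, radius=0.05, precision_digits=16)
        )
        assert 0.0 < e.pvalue < 1.0 and not e.clipped
        assert e.pvalue == pytest.approx(hp, rel=1e-8)
        assert e.cancellation_index < 10.0

    @pytest.mark.parametrize("kind,L,seed", [("grouped", 8, 1), ("grouped", 6, 4), ("near_degenerate", 5, 2)])
    def test_order_convergence(self, kind, L, seed):
        s = generate_fixture(kind, L, seed)
        exact = exact_reference(s)
        cs, moments, t = _pipeline(s, 0.05, 6)
        errs = []
        for k in (0, 2, 3, 4, 5, 6):
            _, _, total, _ = _evaluate(cs, moments, t, k, 50)
            errs.append(abs(float(total) - exact))
        # truncation error shrinks with order (allow float-noise plateau)
        tol = abs(exact) * 1e-14
        assert all(a >= b - tol for a, b in zip(errs, errs[1:]))
        assert errs[-1] <= max(errs[0] * 1e-4, tol)

    def test_sign_sanity_across_fixture_suite(self):
        for kind in ("grouped", "near_degenerate", "symmetric_clusters"):
            for seed in range(5):
                s = generate_fixture(kind, 6, seed)
                e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.05))
                assert 0.0 <= e.raw_value <= 1.0 and not e.clipped


class TestDegenerateSweep:
    def test_transition_from_good_to_fisher(self):
        p = [0.03, 0.2]
        diffs, cancels = [], []
        for eps in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10, 1e-12, 1e-14):
            s = WeightedPValueSet(p, [1.0, 1.0 * (1 + eps)])
            e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.05))
            f = fisher_combine(s)
            g = good_combine(s, digits=16)
            diffs.append(abs(e.pvalue - f.pvalue))
            cancels.append(g.cancellation_index)
        assert all(a > b for a, b in zip(diffs[:-1], diffs[1:]))  # converges to Fisher
        assert diffs[-1] < 1e-14
        assert all(a < b for a, b in zip(cancels, cancels[1:]))  # Good diverges
        assert cancels[-1] > 1e12


class TestTruncationBound:
    def test_zero_deviations_zero_bound(self):
        cs = cluster_inverse_weights([1.0, 1.0, 1.0], 0.0)
        moments = cluster_moments(cs, 4)
        assert truncation_bound(cs, moments, 2.0, 4) == 0.0

    def test_rho_at_least_one_raises(self):
        cs = cluster_inverse_weights([0.01, 0.01, 0.01, 3.97], 5.0)
        moments = cluster_moments(cs, 4)
        assert cs.max_relative_deviation() >= 1.0
        with pytest.raises(BoundUnavailableError):
            truncation_bound(cs, moments, 2.0, 4)

    @pytest.mark.parametrize("kind", ["grouped", "near_degenerate", "symmetric_clusters"])
    def test_bound_dominates_next_orders(self, kind):
        for seed in range(8):
            s = generate_fixture(kind, 7, seed)
            cs, moments, t = _pipeline(s, 0.05, 6)
            if cs.max_relative_deviation() > 0.1:
                continue
            for k in (2, 4):
                _, _, pk, _ = _evaluate(cs, moments, t, k, 50)
                _, _, pk2, _ = _evaluate(cs, moments, t, k + 2, 50)
                bound = truncation_bound(cs, moments, t, k)
                assert bound >= abs(float(pk2 - pk))

    def test_reported_bound_covers_true_error(self):
        for seed in range(6):
            s = generate_fixture("grouped", 6, seed)
            e = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.05))
            exact = exact_reference(s)
            assert abs(e.pvalue - exact) <= e.truncation_bound + 1e-15


class TestAutoRadius:
    def test_auto_meets_accuracy_goal(self):
        s = generate_fixture("grouped", 8, 3)
        cfg = ExpansionConfig(max_order=4, radius="auto", accuracy_goal=1e-10)
        e = expansion_combine(s, cfg)
        exact = exact_reference(s)
        assert e.pvalue == pytest.approx(exact, rel=1e-9, abs=1e-12)

    def test_auto_on_nearly_degenerate_picks_positive_radius(self, nearly_equal_set):
        e = expansion_combine(
            nearly_equal_set, ExpansionConfig(max_order=4, radius="auto")
        )
        hp = good_combine(nearly_equal_set, digits=50).pvalue
        assert e.pvalue == pytest.approx(hp, rel=1e-8)
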