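"""Deterministic model mathematics: ideal responses, RDINA probabilities,
growth logits, quadrature-mixed attribute probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from lgcdm import (
    AttributeGrowthParameters,
    AttributePattern,
    ItemGrowthParameters,
    ItemParameters,
    QMatrix,
    QuadratureRule,
    TimeCoding,
    attribute_logit,
    attribute_patterns,
    guess_slip,
    ideal_response,
    item_growth_logit,
    item_params_from_guess_slip,
    marginal_attribute_prob,
    pattern_prob,
    pattern_prob_table,
    rdina_response_prob,
)


class TestQMatrix:
    def test_rejects_item_without_attributes(self):
        with pytest.raises(ValueError, match="requires no attribute"):
            QMatrix(entries=np.array([[1, 0], [0, 0]]))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            QMatrix(entries=np.array([[2, 0], [1, 1]]))

    def test_warns_when_fewer_items_than_attributes(self):
        with pytest.warns(UserWarning, match="fewer items"):
            QMatrix(entries=np.array([[1, 1, 1]]))

    def test_default_labels(self):
        q = QMatrix(entries=np.eye(2, dtype=int))
        assert q.item_ids == ("Y1", "Y2")
        assert q.attribute_ids == ("a1", "a2")


class TestTimeCoding:
    def test_baseline_must_be_zero(self):
        with pytest.raises(ValueError, match="coded 0"):
            TimeCoding(np.array([1.0, 2.0]))

    def test_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeCoding(np.array([0.0, 2.0, 1.0]))


class TestIdealResponse:
    @pytest.mark.parametrize(
        "alpha,q,expected",
        [
            ((1, 1), (1, 1), 1),   # all required attributes mastered
            ((1, 0), (1, 1), 0),   # one required attribute missing
            ((0, 1), (0, 1), 1),   # non-required attribute ignored
            ((0, 0), (0, 1), 0),
        ],
    )
    def test_conjunctive_rule(self, alpha, q, expected):
        assert ideal_response(np.array(alpha), np.array(q)) == expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            ideal_response(np.array([1, 0]), np.array([1, 0, 1]))

    def test_pattern_space_is_complete(self):
        pats = attribute_patterns(4)
        assert pats.shape == (16, 4)
        assert len({tuple(p) for p in pats}) == 16


class TestRdinaResponseProb:
    def test_zero_logit_gives_half(self):
        item = ItemParameters(f=[0.0], d=[0.0])
        assert rdina_response_prob(item, 0, eta=1) == pytest.approx(0.5)

    def test_false_alarm_and_hit_probabilities(self):
        # direct logistic evaluation on a strongly discriminating item
        item = ItemParameters(f=[-2.09], d=[1.97])
        assert rdina_response_prob(item, 0, eta=0) == pytest.approx(
            expit(-2.09), abs=1e-12
        )
        assert rdina_response_prob(item, 0, eta=0) == pytest.approx(0.110, abs=5e-4)
        assert rdina_response_prob(item, 0, eta=1) == pytest.approx(0.470, abs=5e-4)

    def test_covariate_requires_item_effect(self):
        item = ItemParameters(f=[0.0], d=[1.0])
        with pytest.raises(ValueError, match="covariate"):
            rdina_response_prob(item, 0, eta=1, z=1.0)
        with_l = ItemParameters(f=[0.0], d=[1.0], l=[0.5])
        assert rdina_response_prob(with_l, 0, eta=0, z=1.0) == pytest.approx(
            expit(0.5)
        )

    def test_monotone_in_eta_when_d_nonnegative(self, rng):
        item = ItemParameters(f=rng.normal(0, 2, 10), d=rng.uniform(0, 4, 10))
        for j in range(10):
            assert rdina_response_prob(item, j, 1) >= rdina_response_prob(item, j, 0)


class TestGuessSlip:
    def test_symmetric_point(self):
        g, s = guess_slip(ItemParameters(f=[0.0], d=[0.0]))
        assert g[0] == pytest.approx(0.5)
        assert s[0] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=60)
    @given(
        g=st.floats(0.01, 0.99),
        s=st.floats(0.01, 0.99),
    )
    def test_round_trip(self, g, s):
        item = item_params_from_guess_slip(np.array([g]), np.array([s]))
        g2, s2 = guess_slip(item)
        assert g2[0] == pytest.approx(g, abs=1e-12)
        assert s2[0] == pytest.approx(s, abs=1e-12)


class TestAttributeLogit:
    def test_all_zero(self):
        attr = AttributeGrowthParameters(b=[0.0], sigma0=1.0, sigma1=1.0)
        assert attribute_logit(attr, 0, t=1.0) == 0.0

    def test_conditional_hand_sum(self):
        # difficulty + main effect + treated intercept loading at one SD
        attr = AttributeGrowthParameters(
            b=[-0.45], sigma0=0.46, sigma1=0.03, h=[0.40], h0=0.30, h1=0.09
        )
        got = attribute_logit(attr, 0, t=1.0, z=1.0, zeta=1.0, gamma=0.0)
        assert got == pytest.approx(-0.45 + 0.40 + (0.46 + 0.30) * 1.0)
        # slope factor at one SD contributes the treated slope loading per unit time
        got = attribute_logit(attr, 0, t=1.0, z=1.0, zeta=0.0, gamma=1.0)
        assert got == pytest.approx(-0.45 + 0.40 + (0.03 + 0.09) * 1.0)

    def test_covariate_off_reduces_to_unconditional(self, rng):
        cond = AttributeGrowthParameters(
            b=[0.2, -0.4], sigma0=0.5, sigma1=0.3, h=[0.0, 0.0], h0=0.0, h1=0.0
        )
        unc = AttributeGrowthParameters(b=[0.2, -0.4], sigma0=0.5, sigma1=0.3)
        for _ in range(20):
            k = rng.integers(0, 2)
            t, zeta, gamma, eps = rng.normal(size=4)
            t = abs(t)
            a = attribute_logit(cond, k, t, 1.0, zeta, gamma, eps)
            b = attribute_logit(unc, k, t, 0.0, zeta, gamma, eps)
            assert a == b  # bit-for-bit


class TestMarginalAttributeProb:
    def test_symmetry_gives_half(self):
        attr = AttributeGrowthParameters(b=[0.0], sigma0=0.7, sigma1=0.3)
        p = marginal_attribute_prob(attr, 0, t=1.0)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_strictly_increasing_in_difficulty(self):
        probs = [
            marginal_attribute_prob(
                AttributeGrowthParameters(b=[b], sigma0=0.5, sigma1=0.2), 0, 1.0
            )
            for b in np.linspace(-2, 2, 9)
        ]
        assert np.all(np.diff(probs) > 0)

    def test_degenerate_mixture_is_plain_logistic(self):
        attr = AttributeGrowthParameters(
            b=[0.8], sigma0=0.0, sigma1=0.0, eps_sd=0.0
        )
        assert marginal_attribute_prob(attr, 0, t=1.0) == pytest.approx(
            expit(0.8), abs=1e-14
        )

    @pytest.mark.parametrize("b", [-5.0, -1.0, 0.3, 5.0])
    def test_node_doubling_converged(self, b):
        attr = AttributeGrowthParameters(b=[b], sigma0=1.0, sigma1=1.0, eps_sd=1.0)
        p1 = marginal_attribute_prob(attr, 0, 1.0, quad=QuadratureRule.gauss_hermite(41))
        p2 = marginal_attribute_prob(attr, 0, 1.0, quad=QuadratureRule.gauss_hermite(82))
        assert abs(p1 - p2) < 1e-8

    def test_rejects_tiny_rule(self):
        attr = AttributeGrowthParameters(b=[0.0])
        with pytest.raises(ValueError, match="at least 3"):
            marginal_attribute_prob(attr, 0, 0.0, quad=QuadratureRule.gauss_hermite(2))


class TestPatternProb:
    def test_independent_product(self):
        assert pattern_prob(np.array([0.5, 0.5]), np.array([1, 0])) == pytest.approx(
            0.25
        )

    def test_full_mastery_limit(self):
        p = pattern_prob(np.array([1 - 1e-9, 1 - 1e-9]), np.array([1, 1]))
        assert p == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("K", [1, 2, 4, 6])
    def test_normalizes_over_pattern_space(self, K, rng):
        probs = rng.uniform(0.05, 0.95, K)
        table = pattern_prob_table(probs)
        assert table.shape == (2**K,)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)
        # consistency with the single-pattern evaluator
        pats = attribute_patterns(K)
        for c in rng.choice(2**K, size=min(8, 2**K), replace=False):
            assert table[c] == pytest.approx(
                pattern_prob(probs, AttributePattern(pats[c])), abs=1e-12
            )


class TestItemGrowthLogit:
    def test_all_zero(self):
        igp = ItemGrowthParameters(rho=[0.0], xi_sd=1.0, phi_sd=1.0)
        item = ItemParameters(f=[0.0], d=[0.0])
        assert item_growth_logit(igp, item, 0, eta=0, t=0.0) == 0.0

    def test_reduces_to_measurement_logit(self):
        igp = ItemGrowthParameters(rho=[0.0])
        item = ItemParameters(f=[-1.2], d=[2.5])
        assert item_growth_logit(igp, item, 0, eta=1, t=3.0) == pytest.approx(1.3)

    def test_time_slope_arithmetic(self):
        igp = ItemGrowthParameters(rho=[0.5])
        item = ItemParameters(f=[-1.0], d=[2.0])
        assert item_growth_logit(igp, item, 0, eta=1, t=2.0) == pytest.approx(2.0)


class TestQuadratureRule:
    def test_weights_normalized_and_moments(self):
        q = QuadratureRule.gauss_hermite(15)
        assert q.weights.sum() == pytest.approx(1.0)
        assert q.weights @ q.nodes == pytest.approx(0.0, abs=1e-12)
        assert q.weights @ q.nodes**2 == pytest.approx(1.0, abs=1e-10)
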