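"""Payoff structure, assumption validation and the closed-form ESS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from languse import (
    DomainError,
    EquilibriumDomainError,
    InvalidInputError,
    LocalityRecord,
    PayoffSpec,
    ess_equilibrium,
    expected_payoffs,
    validate_assumptions,
    weighted_benefit,
)
from conftest import random_admissible


class TestValidateAssumptions:
    def test_admissible_linear_family_passes(self):
        spec = PayoffSpec(
            n=1.0,
            alpha_star=0.9,
            m_fn=lambda a: 1.0 + (0.9 - a),
            c_fn=lambda a: 0.1 * (0.9 - a),
        )
        assert validate_assumptions(spec, [0.2, 0.5, 0.8]) == []

    def test_constant_cost_equal_to_n_flagged(self):
        spec = PayoffSpec(
            n=1.0,
            alpha_star=0.9,
            m_fn=lambda a: 1.0 + (0.9 - a),
            c_fn=lambda a: 1.0,
        )
        report = validate_assumptions(spec, [0.3, 0.6])
        assert any("n > c(alpha) > 0" in v for v in report)
        assert any("not strictly decreasing" in v for v in report)

    def test_grid_point_beyond_aspiration_is_domain_error(self, family_spec):
        with pytest.raises(DomainError):
            validate_assumptions(family_spec, [0.5, 0.95])

    def test_grid_point_outside_unit_interval_is_invalid(self, family_spec):
        with pytest.raises(InvalidInputError):
            validate_assumptions(family_spec, [-0.1, 0.5])

    def test_bilingual_majority_country_warns_not_errors(self, family_spec):
        with pytest.warns(UserWarning, match="national minority"):
            report = validate_assumptions(
                family_spec, [0.3, 0.5], country_alpha=0.6
            )
        assert report == []

    def test_weighted_benefit_violation_detected(self):
        # near alpha = 0 the weighted benefit vanishes but a constant cost
        # does not, so the condition c < b must fail there
        spec = PayoffSpec.from_constants(m=2.0, c=0.4, n=1.0)
        report = validate_assumptions(spec, [0.05])
        assert any("weighted-benefit" in v for v in report)


class TestExpectedPayoffs:
    @pytest.mark.parametrize(
        "p, expected_ur, expected_uh",
        [(1.0, 1.3, 1.5), (0.0, 1.3, 1.0)],
    )
    def test_worked_example(self, simple_spec, p, expected_ur, expected_uh):
        u_r, u_h = expected_payoffs(simple_spec, 0.5, p)
        assert u_r == pytest.approx(expected_ur)
        assert u_h == pytest.approx(expected_uh)

    @given(
        p=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_payoff_gap_identity(self, p, seed):
        """u_R - u_H = alpha (1-p) (m-n) - (1-alpha) c for any admissible spec."""
        spec, alpha = random_admissible(np.random.default_rng(seed))
        u_r, u_h = expected_payoffs(spec, alpha, p)
        m, c = spec.m(alpha), spec.c(alpha)
        gap = alpha * (1.0 - p) * (m - spec.n) - (1.0 - alpha) * c
        assert u_r - u_h == pytest.approx(gap, abs=1e-12)

    def test_out_of_range_p_rejected(self, simple_spec):
        with pytest.raises(InvalidInputError):
            expected_payoffs(simple_spec, 0.5, 1.2)

    def test_out_of_range_alpha_rejected(self, simple_spec):
        with pytest.raises(InvalidInputError):
            expected_payoffs(simple_spec, 1.2, 0.5)


class TestEssEquilibrium:
    def test_worked_example(self, simple_spec):
        eq = ess_equilibrium(simple_spec, 0.5)
        assert eq.p_star == pytest.approx(0.6)
        assert eq.shift_prob == pytest.approx(0.16)
        assert eq.use_prob_bilingual_pair == pytest.approx(0.84)
        assert eq.rest_points == (
            (0.0, "unstable"),
            (0.6, "stable"),
            (1.0, "unstable"),
        )

    def test_second_worked_example(self):
        spec = PayoffSpec.from_constants(m=3.0, c=0.3, n=1.0)
        assert ess_equilibrium(spec, 0.2).p_star == pytest.approx(0.4)

    def test_zero_cost_limit_gives_full_reveal(self):
        for c in (1e-3, 1e-6, 1e-9):
            spec = PayoffSpec.from_constants(m=2.0, c=c, n=1.0)
            eq = ess_equilibrium(spec, 0.5)
            assert eq.p_star == pytest.approx(1.0, abs=2 * c)
        assert ess_equilibrium(spec, 0.5).shift_prob < 1e-17

    def test_weighted_benefit_violation_raises(self):
        # c >= b would push p* out of (0, 1)
        spec = PayoffSpec.from_constants(m=2.0, c=0.9, n=1.0)
        with pytest.raises(EquilibriumDomainError):
            ess_equilibrium(spec, 0.3)  # b = 1*0.3/0.7 = 0.43 < 0.9

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_ess_conditions(self, seed):
        """p* in (0,1); indifference at p*; R favoured below, H above (ESS)."""
        spec, alpha = random_admissible(np.random.default_rng(seed))
        eq = ess_equilibrium(spec, alpha)
        p = eq.p_star
        assert 0 < p < 1
        u_r, u_h = expected_payoffs(spec, alpha, p)
        assert u_r == pytest.approx(u_h, abs=1e-12)
        u_r_lo, u_h_lo = expected_payoffs(spec, alpha, max(p - 0.05, 0.0))
        u_r_hi, u_h_hi = expected_payoffs(spec, alpha, min(p + 0.05, 1.0))
        assert u_r_lo > u_h_lo
        assert u_r_hi < u_h_hi

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_probability_closure(self, seed):
        spec, alpha = random_admissible(np.random.default_rng(seed))
        eq = ess_equilibrium(spec, alpha)
        assert eq.shift_prob + eq.use_prob_bilingual_pair == pytest.approx(
            1.0, abs=1e-15
        )

    def test_comparative_statics(self):
        """p* increases in m and decreases in c."""
        alpha = 0.4
        base = ess_equilibrium(
            PayoffSpec.from_constants(m=2.0, c=0.2, n=1.0), alpha
        ).p_star
        more_benefit = ess_equilibrium(
            PayoffSpec.from_constants(m=2.5, c=0.2, n=1.0), alpha
        ).p_star
        more_cost = ess_equilibrium(
            PayoffSpec.from_constants(m=2.0, c=0.3, n=1.0), alpha
        ).p_star
        assert more_benefit > base > more_cost


class TestWeightedBenefit:
    def test_worked_example(self, simple_spec):
        assert weighted_benefit(simple_spec, 0.5) == pytest.approx(1.0)

    def test_vanishes_as_alpha_to_zero(self, simple_spec):
        assert weighted_benefit(simple_spec, 1e-6) < 2e-6

    def test_zero_preference_intensity(self):
        spec = PayoffSpec.from_constants(m=1.0, c=0.1, n=1.0)
        assert weighted_benefit(spec, 0.5) == 0.0

    def test_domain_error_beyond_aspiration(self, simple_spec):
        with pytest.raises(DomainError):
            weighted_benefit(simple_spec, 0.95)


class TestLocalityRecord:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            LocalityRecord("x", 2016, 100, 1.5, 0.2, "street")
        with pytest.raises(InvalidInputError):
            LocalityRecord("x", 2016, 100, 0.5, 1.2, "street")
        with pytest.raises(InvalidInputError):
            LocalityRecord("x", 2016, -1, 0.5, 0.2, "street")
        with pytest.raises(InvalidInputError):
            LocalityRecord("x", 2016, 100, 0.5, 0.2, "weekly")


class TestPayoffSpecFamily:
    def test_family_limits_at_aspiration(self):
        spec = PayoffSpec.from_family(mu=2.0, kappa=0.5, a=1.5, d=2.0)
        a = 0.9 - 1e-7
        assert spec.m(a) == pytest.approx(spec.n, abs=1e-9)
        assert spec.c(a) == pytest.approx(0.0, abs=1e-9)

    def test_family_rejects_nonpositive_parameters(self):
        with pytest.raises(InvalidInputError):
            PayoffSpec.from_family(mu=-1.0, kappa=0.5)

    def test_invalid_n_rejected(self):
        with pytest.raises(InvalidInputError):
            PayoffSpec.from_constants(m=2.0, c=0.1, n=0.0)
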