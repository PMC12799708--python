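"""Limit theory: escape rate, composition, velocity, and their identities.

Frozen expected values for the near-critical two-monomer set were
computed with an independent 200-iteration bisection on
g(m) = sum_r k_r^+/(m + k_r^-) = 1 and direct evaluation of the closed
forms, before this module existed.
"""

import numpy as np
import pytest

from copolymer import (
    AnalyticSummary,
    RateParameters,
    RegimeError,
    analytic_summary,
    boundary_transition_matrix,
    cone_visit_fractions,
    d2_closed_form,
    dtmc_speed,
    first_return_probs,
    green_ratio_matrix,
    growth_velocity,
    limiting_composition,
    solve_escape_rate,
)
from copolymer.analytic import escape_rate_equation

from conftest import random_transient_params

# frozen bisection-oracle values for kplus=(1, 1.2), kminus=(1.8, 2.592)
M_ORACLE = 0.03873168634704072
F_ORACLE = (0.9789356507887305, 0.9852772190535241)
SIGMA_ORACLE = (0.5438531393270725, 0.45614686067292776)
CHI_ORACLE = (0.49880273371352923, 0.5011972662864708)
R12_ORACLE = 1.004800560243755
VBAR_ORACLE = 0.008880830887150658


class TestEscapeRate:
    def test_d1_closed_form(self, birth_death_params):
        # k+/(m + k-) = 1 gives m = k+ - k-
        assert solve_escape_rate(birth_death_params) == pytest.approx(2.0, abs=1e-12)

    def test_near_critical_matches_bisection_oracle(self, near_critical_params):
        assert solve_escape_rate(near_critical_params) == pytest.approx(M_ORACLE, abs=1e-12)

    def test_defining_property(self, strong_params):
        m = solve_escape_rate(strong_params)
        assert escape_rate_equation(strong_params, m) == pytest.approx(1.0, abs=1e-10)

    def test_regime_error(self, recurrent_params):
        with pytest.raises(RegimeError):
            solve_escape_rate(recurrent_params)


class TestFirstReturn:
    def test_d1_biased_walk_ratio(self, birth_death_params):
        np.testing.assert_allclose(first_return_probs(birth_death_params), [1 / 3],
                                   atol=1e-12)

    def test_near_critical(self, near_critical_params):
        np.testing.assert_allclose(first_return_probs(near_critical_params),
                                   F_ORACLE, atol=1e-10)

    def test_fixed_point_residual(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_transient_params(rng)
            F = first_return_probs(p)
            kp, km = p.kplus_array(), p.kminus_array()
            residual = km / ((km + p.total_attach) - np.sum(kp * F)) - F
            assert np.max(np.abs(residual)) < 1e-12
            assert np.all((F > 0) & (F < 1))


class TestComposition:
    def test_near_critical_printed_precision(self, near_critical_params):
        sigma = limiting_composition(near_critical_params)
        np.testing.assert_allclose(sigma, [0.5436, 0.4564], atol=1e-3)

    def test_near_critical_full_precision(self, near_critical_params):
        np.testing.assert_allclose(limiting_composition(near_critical_params),
                                   SIGMA_ORACLE, atol=1e-12)

    def test_equal_detachment_reduces_to_attach_ratio(self):
        p = RateParameters(kplus=(2.0, 1.0), kminus=(0.5, 0.5))
        np.testing.assert_allclose(limiting_composition(p), [2 / 3, 1 / 3], atol=1e-12)

    def test_sums_to_one(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sigma = limiting_composition(random_transient_params(rng))
            assert sigma.sum() == pytest.approx(1.0, abs=1e-10)


class TestBoundaryMatrix:
    def test_rows_equal_sigma(self, near_critical_params):
        V = boundary_transition_matrix(near_critical_params)
        sigma = limiting_composition(near_critical_params)
        np.testing.assert_allclose(V, np.tile(sigma, (2, 1)), atol=1e-12)
        np.testing.assert_allclose(V.sum(axis=1), [1.0, 1.0], atol=1e-10)

    def test_reduced_form(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = random_transient_params(rng)
            V = boundary_transition_matrix(p)
            F = first_return_probs(p)
            reduced = F * p.kplus_array() / p.kminus_array()
            np.testing.assert_allclose(V, np.tile(reduced, (p.d, 1)), atol=1e-12)
            assert np.all(V > 0)


class TestVelocityAndSpeed:
    def test_d1_net_rate(self, birth_death_params):
        assert growth_velocity(birth_death_params) == pytest.approx(2.0, abs=1e-12)
        assert dtmc_speed(birth_death_params) == pytest.approx(0.5, abs=1e-12)

    def test_near_critical_printed_precision(self, near_critical_params):
        assert growth_velocity(near_critical_params) == pytest.approx(0.0382, abs=1e-3)
        assert dtmc_speed(near_critical_params) == pytest.approx(VBAR_ORACLE, abs=1e-12)

    def test_velocity_equals_escape_rate(self):
        # derived identity: substituting sigma_r = k_r+/(m+k_r-) collapses v to m
        rng = np.random.default_rng(14)
        for _ in range(20):
            p = random_transient_params(rng)
            assert growth_velocity(p) == pytest.approx(solve_escape_rate(p), abs=1e-12)

    def test_speed_consistency_chain(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            p = random_transient_params(rng)
            sigma = limiting_composition(p)
            weight = float(np.sum(sigma * (p.kminus_array() + p.total_attach)))
            vbar = dtmc_speed(p)
            assert 0 < vbar < 1
            assert growth_velocity(p) == pytest.approx(vbar * weight, abs=1e-12)


class TestConeVisitAndGreen:
    def test_symmetric_types_give_uniform_fractions(self):
        p = RateParameters(kplus=(2.0, 2.0, 2.0), kminus=(1.0, 1.0, 1.0))
        np.testing.assert_allclose(cone_visit_fractions(p), np.full(3, 1 / 3), atol=1e-12)

    def test_near_critical_values(self, near_critical_params):
        np.testing.assert_allclose(cone_visit_fractions(near_critical_params),
                                   CHI_ORACLE, atol=1e-10)
        R = green_ratio_matrix(near_critical_params)
        assert R[0, 1] == pytest.approx(R12_ORACLE, abs=1e-10)

    def test_green_ratio_structure(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            p = random_transient_params(rng)
            R = green_ratio_matrix(p)
            np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
            np.testing.assert_allclose(R * R.T, 1.0, atol=1e-10)
            np.testing.assert_allclose(cone_visit_fractions(p), 1.0 / R.sum(axis=1),
                                       atol=1e-12)


class TestD2ClosedForm:
    def test_matches_solver_near_critical(self, near_critical_params):
        np.testing.assert_allclose(d2_closed_form(near_critical_params),
                                   limiting_composition(near_critical_params),
                                   atol=1e-10)

    def test_equal_detachment_branch(self, strong_params):
        np.testing.assert_allclose(d2_closed_form(strong_params), [2 / 3, 1 / 3],
                                   atol=1e-15)

    def test_dimension_error(self, birth_death_params):
        with pytest.raises(ValueError):
            d2_closed_form(birth_death_params)

    def test_random_sweep(self):
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(200):
            p = random_transient_params(rng, d=2)
            diff = np.abs(d2_closed_form(p) - limiting_composition(p))
            worst = max(worst, float(diff.max()))
        assert worst < 1e-8


class TestSummary:
    def test_transient_fully_populated(self, near_critical_params):
        s = analytic_summary(near_critical_params)
        assert s.regime == "transient"
        for name in ("m", "F", "sigma_bar", "V", "v", "v_bar", "chi_limit", "R"):
            assert s.require(name) is not None

    def test_recurrent_fields_absent(self, recurrent_params):
        s = analytic_summary(recurrent_params)
        assert s.regime == "positive_recurrent"
        assert s.m is None and s.sigma_bar is None
        with pytest.raises(RegimeError):
            s.require("sigma_bar")

    def test_json_round_trip(self, near_critical_params, tmp_path):
        s = analytic_summary(near_critical_params)
        path = tmp_path / "summary.json"
        s.to_json(path)
        s2 = AnalyticSummary.from_json(path)
        assert s2.params == s.params
        assert s2.regime == s.regime
        assert s2.m == s.m and s2.v == s.v and s2.v_bar == s.v_bar
        for name in ("F", "sigma_bar", "V", "chi_limit", "R"):
            np.testing.assert_array_equal(getattr(s2, name), getattr(s, name))
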