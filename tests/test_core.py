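"""Unit and property tests for the cell-level flux budget."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixotroph import (
    Environment,
    ModelParams,
    TraitSet,
    affinity,
    basal_respiration,
    compute_budget,
    growth_rate,
    growth_rate_arrays,
    light_energy_factor,
    max_uptake,
    potential_uptake,
)
from mixotroph.core import _growth_scalar

from conftest import random_envs, random_traits

V = 6.5e-5


class TestTradeoffs:
    def test_affinity_zero_investment_is_zero(self, params):
        assert affinity(0.0, params.A_max_N, params.alpha_N, params.V) == 0.0

    def test_affinity_matches_hand_arithmetic(self, params):
        # A_N at phi_N = 0.1: 1e-6 * (0.30*0.1*6.5e-5) / (0.30*0.1*6.5e-5 + 1e-6)
        a = affinity(0.1, params.A_max_N, params.alpha_N, params.V)
        assert a == pytest.approx(6.610e-7, rel=1e-3)

    def test_affinity_saturates_at_maximum(self, params):
        a = affinity(1e3, params.A_max_F, params.alpha_F, params.V)
        assert a == pytest.approx(params.A_max_F, rel=0.01)

    def test_affinity_strictly_increasing_and_concave(self, params):
        phis = np.linspace(0.0, 1.0, 21)
        a = affinity(phis, params.A_max_L, params.alpha_L, params.V)
        assert np.all(np.diff(a) > 0)
        assert np.all(np.diff(a, 2) < 0)

    @given(st.floats(0.001, 1.0), st.floats(0.1, 10.0))
    def test_affinity_scale_invariance(self, phi, c):
        """affinity(phi)/A_max is unchanged under (alpha -> c*alpha, phi -> phi/c)."""
        p = ModelParams()
        a1 = affinity(phi, p.A_max_F, p.alpha_F, p.V)
        a2 = affinity(phi / c, p.A_max_F, p.alpha_F * c, p.V)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_affinity_rejects_negative_investment(self, params):
        with pytest.raises(ValueError):
            affinity(-0.1, params.A_max_N, params.alpha_N, params.V)

    def test_max_uptake_linear_and_matches_table(self, params):
        assert max_uptake(0.0, params.M_F, params.V) == 0.0
        # K. armiger phagotrophy capacity: 14.10 * 0.16 * 6.5e-5
        assert max_uptake(0.16, params.M_F, params.V) == pytest.approx(1.4664e-4, rel=1e-12)
        assert max_uptake(0.32, params.M_F, params.V) == pytest.approx(
            2 * max_uptake(0.16, params.M_F, params.V))


class TestFunctionalResponse:
    def test_zero_resource_gives_zero_uptake(self):
        assert potential_uptake(1e-6, 1e-4, 0.0) == 0.0

    def test_half_saturation_identity(self):
        A, Jmax = 3e-7, 1.2e-4
        assert potential_uptake(A, Jmax, Jmax / A) == pytest.approx(Jmax / 2, rel=1e-12)

    def test_saturation_limit(self):
        A, Jmax = 3e-7, 1.2e-4
        assert potential_uptake(A, Jmax, 1e15) == pytest.approx(Jmax, rel=1e-6)

    def test_zero_over_zero_convention(self):
        assert potential_uptake(0.0, 0.0, 0.0) == 0.0
        assert potential_uptake(0.0, 1e-4, 5.0) == 0.0


class TestRespirationAndThrottle:
    def test_basal_respiration_values(self, params):
        assert basal_respiration(TraitSet(0, 0, 0), params) == pytest.approx(3.25e-6)
        ven = TraitSet(0.45, 0.08, 0.10)
        assert basal_respiration(ven, params) == pytest.approx(0.05 * 1.63 * V, rel=1e-12)
        # investments-only variant for sensitivity analysis
        assert basal_respiration(ven, params, include_structure=False) == pytest.approx(
            0.05 * 0.63 * V, rel=1e-12)

    def test_rho_zero_in_darkness(self, params):
        assert light_energy_factor(0.0, 3e-6, 0.0, 1e-4, params) == 0.0

    def test_rho_clamps_to_one_at_saturating_light(self, params):
        # K. armiger at saturating light and food, fluxes in units of V
        rho = light_energy_factor(2.2545 * V, 0.0805 * V, 0.0, 2.256 * V, params)
        assert rho == 1.0

    def test_rho_one_when_nothing_to_throttle(self, params):
        assert light_energy_factor(1e-4, 3e-6, 0.0, 0.0, params) == 1.0

    @given(st.floats(0, 1e-3), st.floats(0, 1e-4), st.floats(0, 1e-3), st.floats(0, 1e-3))
    def test_rho_bounded(self, J_L, J_R, Jpot_N, Jpot_F):
        rho = light_energy_factor(J_L, J_R, Jpot_N, Jpot_F, ModelParams())
        assert 0.0 <= rho <= 1.0


class TestBudget:
    def test_zero_investment_cell_shrinks_at_basal_rate(self, params):
        b = compute_budget(TraitSet(0, 0, 0), Environment(100, 50, 200), params)
        assert b.mu == pytest.approx(-params.r_0, abs=1e-15)
        assert b.g == pytest.approx(-0.17, abs=1e-12)

    def test_veneficum_saturating_monoculture_pin(self, params):
        """Hand-chained oracle: J_N=0.1V, J_tot = c_CN*0.1V, mu = 0.568/1.63."""
        b = compute_budget(TraitSet(0.45, 0.08, 0.10), Environment(1e7, 1e7, 0.0), params)
        expected_mu = params.c_CN * 0.10 / 1.63
        assert b.mu == pytest.approx(expected_mu, rel=1e-3)
        assert b.g == pytest.approx(expected_mu - params.m, rel=2e-3)
        assert b.J_tot == pytest.approx(params.c_CN * b.J_N, rel=1e-12)  # N-limited branch

    def test_armiger_cannot_grow_without_food(self, params):
        for X_L in (0.0, 10.0, 1000.0):
            b = compute_budget(TraitSet(0.45, 0.16, 0.0), Environment(X_L, 1e7, 0.0), params)
            assert b.N_syn == 0.0
            assert b.J_tot <= 0.0
            assert b.g < 0.0

    def test_dark_limit_no_uptake_and_death(self, params, rng):
        for row in random_traits(rng, 20):
            traits = TraitSet(*row)
            b = compute_budget(traits, Environment(0.0, 100.0, 500.0), params)
            assert b.J_F == 0.0 and b.J_N == 0.0
            assert b.g == pytest.approx(-params.r_0 - params.m, abs=1e-15)

    def test_growth_monotone_in_light_and_food(self, params, rng):
        """More light or food never hurts a fixed strategy.  (More DIN can:
        a carbon-limited cell pays beta_N for nitrogen it must excrete, so
        fixed-trait growth is deliberately not asserted monotone in X_N.)"""
        traits = TraitSet(0.4, 0.2, 0.1)
        base = Environment(50.0, 5.0, 50.0)
        for field_ in ("X_L", "X_F"):
            vals = np.sort(10 ** rng.uniform(-1, 3, 30))
            g = [growth_rate(traits, base.replace(**{field_: float(v)}), params) for v in vals]
            assert np.all(np.diff(g) >= -1e-12)

    def test_growth_monotone_in_nitrogen_when_nitrogen_limited(self, params):
        """With little light-independent carbon pressure (small phi_N, ample
        light), extra DIN relieves nitrogen limitation and raises growth."""
        traits = TraitSet(0.45, 0.0, 0.10)
        vals = np.logspace(-1, 2, 25)
        g = [growth_rate(traits, Environment(1e4, float(v), 0.0), params) for v in vals]
        assert np.all(np.diff(g) >= -1e-12)

    def test_saturation_plateau(self, params):
        traits = TraitSet(0.4, 0.2, 0.2)
        g1 = growth_rate(traits, Environment(1e9, 1e9, 1e9), params)
        g2 = growth_rate(traits, Environment(1e12, 1e12, 1e12), params)
        assert math.isfinite(g1)
        assert g1 == pytest.approx(g2, rel=1e-6)

    def test_mu_equals_g_plus_m(self, params, rng):
        for row, env in zip(random_traits(rng, 10), random_envs(rng, 10)):
            b = compute_budget(TraitSet(*row), env, params)
            assert b.mu == pytest.approx(b.g + params.m, abs=1e-15)

    def test_budget_invariant_bounds(self, params, rng):
        for row, env in zip(random_traits(rng, 50), random_envs(rng, 50)):
            b = compute_budget(TraitSet(*row), env, params)
            assert 0.0 <= b.rho <= 1.0
            assert 0.0 <= b.J_N <= b.Jpot_N + 1e-18
            assert 0.0 <= b.J_F <= b.Jpot_F + 1e-18
            assert b.J_L <= b.Jmax_L + 1e-18
            assert b.excreted_C >= -1e-18 and b.excreted_N >= -1e-18

    def test_carbon_and_nitrogen_ledgers_close(self, params, rng):
        for row, env in zip(random_traits(rng, 200), random_envs(rng, 200)):
            b = compute_budget(TraitSet(*row), env, params)
            scale = max(abs(b.J_L), abs(b.J_F), abs(b.J_R), 1e-30)
            lhs_C = b.J_L + b.J_F
            rhs_C = (params.beta_L * b.J_L + b.J_R + params.beta_N * b.J_N
                     + params.beta_F * b.J_F + b.J_tot + b.excreted_C)
            assert abs(lhs_C - rhs_C) <= 1e-12 * scale
            lhs_N = b.J_N + b.J_F / params.c_CN
            rhs_N = b.J_tot / params.c_CN + b.excreted_N
            assert abs(lhs_N - rhs_N) <= 1e-12 * max(scale / params.c_CN, 1e-30)

    def test_vectorized_and_scalar_paths_agree(self, params, rng):
        phis = random_traits(rng, 64)
        envs = random_envs(rng, 64)
        X = np.array([[e.X_L, e.X_N, e.X_F] for e in envs])
        g_vec = growth_rate_arrays(phis[:, 0], phis[:, 1], phis[:, 2],
                                   X[:, 0], X[:, 1], X[:, 2], params)
        for i in range(64):
            g_s = _growth_scalar(*phis[i], *X[i], params)
            g_b = growth_rate(TraitSet(*phis[i]), envs[i], params)
            assert g_vec[i] == pytest.approx(g_s, rel=1e-12, abs=1e-15)
            assert g_vec[i] == pytest.approx(g_b, rel=1e-12, abs=1e-15)


class TestTypes:
    def test_traitset_feasibility(self):
        with pytest.raises(ValueError):
            TraitSet(-0.1, 0.2, 0.2)
        with pytest.raises(ValueError):
            TraitSet(0.5, 0.4, 0.2)  # sum 1.1 exceeds structural mass
        assert TraitSet(0.5, 0.4, 0.1).total == pytest.approx(1.0)

    def test_environment_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            Environment(-1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            Environment(float("nan"), 0.0, 0.0)

    def test_params_defaults_match_reference_table(self, params):
        expected = dict(V=6.5e-5, A_max_L=4.07e-6, A_max_N=1e-6, A_max_F=4.65e-7,
                        alpha_N=0.30, alpha_F=0.16, M_L=5.01, M_N=1.00, M_F=14.10,
                        beta_L=0.35, beta_N=3.00, beta_F=0.50, r_0=0.05, m=0.12,
                        c_CN=5.68)
        for key, value in expected.items():
            assert getattr(params, key) == value

    def test_params_mapping_roundtrip_and_unknown_key(self, params):
        assert ModelParams.from_mapping(params.to_dict()) == params
        with pytest.raises(ValueError, match="A_max_X"):
            ModelParams.from_mapping({"A_max_X": 1.0})
        with pytest.raises(ValueError):
            ModelParams(beta_L=1.2)
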