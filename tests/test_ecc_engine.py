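import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decfba import (
    EccPolicy,
    EnzymeState,
    bounds_from_composition,
    build_toy_overflow_model,
    composition_difference,
    composition_from_flux,
    ecc_step,
    interpolate_composition,
    interpolation_alpha,
    solve_fba,
)

nonneg_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8
)


class TestComposition:
    def test_mass_is_cost_times_flux(self, toy_model):
        v = np.zeros(toy_model.n_reactions)
        j = toy_model.reaction_index("RESP")
        v[j] = 10.0
        m = composition_from_flux(toy_model, v)
        assert m.m[j] == pytest.approx(toy_model.enzyme_cost[j] * 10.0)
        assert m.m[toy_model.reaction_index("EX_glc")] == 0.0

    def test_zero_flux_zero_mass(self, toy_model):
        m = composition_from_flux(toy_model, np.zeros(toy_model.n_reactions))
        assert np.all(m.m == 0.0)

    def test_negative_costly_flux_is_an_error(self, toy_model):
        v = np.zeros(toy_model.n_reactions)
        v[toy_model.reaction_index("FERM")] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            composition_from_flux(toy_model, v)

    def test_optimum_at_tight_pool_saturates_budget(self, toy_model):
        """At the overflow optimum the pool constraint binds, so the
        implied composition uses exactly the whole budget."""
        sol = solve_fba(toy_model)
        m = composition_from_flux(toy_model, sol.v)
        assert m.total_mass == pytest.approx(toy_model.pool, abs=1e-8)


class TestDifferenceAndAlpha:
    def test_identical_compositions_have_zero_demand(self):
        m = np.array([0.01, 0.02])
        m_d, demand = composition_difference(m, m)
        assert np.all(m_d == 0.0) and demand == 0.0

    def test_swap_demand_counts_only_acquisition(self):
        m_d, demand = composition_difference(np.array([0.02, 0.0]), np.array([0.0, 0.02]))
        assert np.allclose(m_d, [0.02, -0.02])
        assert demand == pytest.approx(0.02)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(nonneg_vectors, nonneg_vectors)
    def test_demand_equals_positive_part_sum(self, a, b):
        n = min(len(a), len(b))
        mo, mp = np.array(a[:n]), np.array(b[:n])
        _, demand = composition_difference(mo, mp)
        assert demand == pytest.approx(sum(max(x - y, 0.0) for x, y in zip(mo, mp)))

    @pytest.mark.parametrize(
        "demand,gamma,dt,expected",
        [
            (0.04, 0.01, 1.0, 0.25),
            (0.005, 0.01, 1.0, 1.0),
            (0.04, 0.0, 1.0, 0.0),   # frozen composition
            (0.0, 0.0, 1.0, 1.0),    # nothing to change
            (0.02, 0.01, 0.5, 0.25),
        ],
    )
    def test_alpha_cases(self, demand, gamma, dt, expected):
        assert interpolation_alpha(demand, gamma, dt) == pytest.approx(expected)


class TestInterpolation:
    def test_alpha_one_adopts_target(self):
        mo = EnzymeState(np.array([0.02, 0.0]))
        mp = EnzymeState(np.array([0.0, 0.02]))
        assert np.array_equal(interpolate_composition(mo, mp, 1.0).m, mo.m)
        assert np.array_equal(interpolate_composition(mo, mp, 0.0).m, mp.m)

    def test_partial_step_spends_exactly_the_budget(self):
        """With alpha = gamma*dt/demand the acquired mass equals gamma*dt."""
        mo = EnzymeState(np.array([0.02, 0.0]))
        mp = EnzymeState(np.array([0.0, 0.02]))
        _, demand = composition_difference(mo, mp)
        gamma, dt = 0.005, 1.0
        alpha = interpolation_alpha(demand, gamma, dt)
        mt = interpolate_composition(mo, mp, alpha)
        acquired = np.clip(mt.m - mp.m, 0.0, None).sum()
        assert acquired == pytest.approx(gamma * dt, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(nonneg_vectors, nonneg_vectors, st.floats(min_value=0, max_value=1))
    def test_convex_combination_bounds_total_mass(self, a, b, alpha):
        n = min(len(a), len(b))
        mo, mp = EnzymeState(np.array(a[:n])), EnzymeState(np.array(b[:n]))
        mt = interpolate_composition(mo, mp, alpha)
        assert np.all(mt.m >= 0.0)
        assert mt.total_mass <= max(mo.total_mass, mp.total_mass) + 1e-12


class TestBoundsFromComposition:
    def test_inverts_composition(self, toy_model):
        j = toy_model.reaction_index("RESP")
        m = np.zeros(toy_model.n_reactions)
        m[j] = 0.01
        ub = bounds_from_composition(toy_model, m)
        assert ub["RESP"][1] == pytest.approx(0.01 / toy_model.enzyme_cost[j])
        assert ub["FERM"][1] == 0.0  # no mass: reaction disabled
        assert "EX_glc" not in ub    # cost-free reactions untouched

    def test_mass_on_costfree_reaction_is_inconsistent(self, toy_model):
        m = np.zeros(toy_model.n_reactions)
        m[toy_model.reaction_index("EX_glc")] = 0.01
        with pytest.raises(ValueError, match="zero cost"):
            bounds_from_composition(toy_model, m)

    def test_own_optimal_composition_is_a_fixed_point(self, toy_model):
        sol = solve_fba(toy_model, pfba=True)
        m = composition_from_flux(toy_model, sol.v)
        again = solve_fba(toy_model, bounds_from_composition(toy_model, m), pfba=True)
        assert again.mu == pytest.approx(sol.mu, abs=1e-8)


class TestEccStep:
    def test_unconstrained_sentinel_matches_plain_solve(self, toy_model):
        plain = solve_fba(toy_model, pfba=True)
        m_prev = EnzymeState(np.zeros(toy_model.n_reactions))
        sol, m_t, diag = ecc_step(toy_model, m_prev, EccPolicy(-1), 0.1, pfba=True)
        assert sol.mu == plain.mu
        assert np.array_equal(sol.v, plain.v)
        assert not diag.constrained

    def test_first_step_initializes_from_optimum(self, toy_model):
        sol, m_t, diag = ecc_step(toy_model, None, EccPolicy(0.01), 0.1, pfba=True)
        expected = composition_from_flux(toy_model, sol.v)
        assert np.allclose(m_t.m, expected.m)
        assert not diag.constrained

    def test_frozen_composition_blocks_the_shift(self, toy_model):
        """A culture with only glucose enzymes, frozen composition, and no
        glucose cannot grow: the acetate route has no capacity yet."""
        sol_glc = solve_fba(toy_model, pfba=True)
        m_prev = composition_from_flux(toy_model, sol_glc.v)
        overrides = {"EX_glc": (0.0, 0.0), "EX_ac": (-1000.0, None)}
        sol, m_t, diag = ecc_step(
            toy_model, m_prev, EccPolicy(0.0), 0.1, overrides, pfba=True
        )
        assert diag.constrained
        assert sol.mu == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(m_t.m, m_prev.m)

    def test_budget_spent_with_equality_when_binding(self, toy_model):
        sol_glc = solve_fba(toy_model, pfba=True)
        m_prev = composition_from_flux(toy_model, sol_glc.v)
        gamma, dt = 0.01, 0.1
        overrides = {"EX_glc": (0.0, 0.0), "EX_ac": (-1000.0, None)}
        sol, m_t, diag = ecc_step(
            toy_model, m_prev, EccPolicy(gamma), dt, overrides, pfba=True
        )
        assert diag.constrained and diag.alpha < 1
        acquired = np.clip(m_t.m - m_prev.m, 0.0, None).sum()
        assert acquired == pytest.approx(gamma * dt, abs=1e-9)

    def test_matches_independent_reimplementation_of_procedure(self, toy_model):
        """Duplicate the interpolate-and-resolve procedure step by step with
        separate code and compare the resulting acetate capacity."""
        sol_glc = solve_fba(toy_model, pfba=True)
        m_prev = composition_from_flux(toy_model, sol_glc.v)
        gamma, dt = 0.02, 0.25
        overrides = {"EX_glc": (0.0, 0.0), "EX_ac": (-1000.0, None)}

        # independent re-derivation
        sol1 = solve_fba(toy_model, overrides, pfba=True)
        m_o = toy_model.enzyme_cost * sol1.v
        demand = float(np.sum(np.maximum(m_o - m_prev.m, 0.0)))
        assert demand > gamma * dt  # the step must actually be constrained
        alpha = gamma * dt / demand
        m_expected = alpha * m_o + (1 - alpha) * m_prev.m
        j = toy_model.reaction_index("ACUP")
        expected_cap = m_expected[j] / toy_model.enzyme_cost[j]

        sol, m_t, diag = ecc_step(
            toy_model, m_prev, EccPolicy(gamma), dt, overrides, pfba=True
        )
        assert diag.alpha == pytest.approx(alpha, abs=1e-12)
        assert m_t.m[j] / toy_model.enzyme_cost[j] == pytest.approx(expected_cap, abs=1e-10)
        assert sol.v[j] <= expected_cap + 1e-8

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            EccPolicy(-0.5)
        assert EccPolicy(-1).unconstrained
        assert not EccPolicy(0.0).unconstrained
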