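import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import sidyn
from sidyn import (
    CultureConditions,
    KineticParameters,
    build_initial_state,
    conservation_law_matrix,
    conservation_residuals,
    mm_rate,
    n_independent_species,
    rhs,
    simulate,
)
from sidyn.model import N_STATE_VARIABLES, STATE_NAMES, jac_params, jac_state

from reference import rk4_trajectory


class TestMMRate:
    def test_half_saturation_by_definition(self):
        assert mm_rate(8.0, 0.5, 8.0) == pytest.approx(0.25)

    def test_zero_substrate_gives_zero_rate(self):
        assert mm_rate(8.0, 0.5, 0.0) == 0.0

    def test_saturation_limit(self):
        K, vmax = 3.0, 1.7
        assert abs(mm_rate(K, vmax, 1e6 * K) - vmax) < 1e-4 * vmax

    @given(
        K=st.floats(0.01, 100.0),
        vmax=st.floats(0.0, 10.0),
        s=st.floats(0.0, 1e4),
        ds=st.floats(0.0, 1e3),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, K, vmax, s, ds):
        r1, r2 = mm_rate(K, vmax, s), mm_rate(K, vmax, s + ds)
        assert 0.0 <= r1 <= r2 <= vmax

    @pytest.mark.parametrize("bad", [dict(K=0.0), dict(K=-1.0), dict(s=-0.1)])
    def test_domain_errors(self, bad):
        kwargs = dict(K=1.0, vmax=1.0, s=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            mm_rate(kwargs["K"], kwargs["vmax"], kwargs["s"])


class TestInitialState:
    def test_starved_initial_condition(self, params):
        cond = CultureConditions(S1_0=100.0)
        y0 = build_initial_state(params, cond)
        assert y0[STATE_NAMES.index("S1")] == 100.0
        for name in ("S2", "S3", "S4", "C1", "C2", "C3", "U"):
            assert y0[STATE_NAMES.index(name)] == 0.0
        for i, name in enumerate(("E1", "E2", "E3")):
            assert y0[STATE_NAMES.index(name)] == params.E0[i]


class TestRHS:
    def test_zero_rates_give_zero_derivative(self, conditions):
        # vanishing turnover makes all derived mass-action constants vanish
        p = KineticParameters(kcat1=1e-300, kcat2=1e-300, kcat3=1e-300)
        y = build_initial_state(p, conditions)
        dy = rhs(0.0, y, p, conditions)
        assert np.allclose(dy, 0.0, atol=1e-290)

    def test_isolated_deposition_step(self, conditions):
        # only step 3 active, complex pre-loaded: deposition at kcat3 * C3
        p = KineticParameters(kcat1=1e-300, kcat2=1e-300, kcat3=5.0)
        y = build_initial_state(p, conditions)
        c3 = 0.012
        y[STATE_NAMES.index("C3")] = c3
        y[STATE_NAMES.index("S3")] = 0.0
        dy = rhs(10.0, y, p, conditions)
        assert dy[STATE_NAMES.index("S4")] == pytest.approx(p.kcat3 * c3)
        # enzyme totals unchanged: dE_i + dC_i = 0
        for e, c in (("E1", "C1"), ("E2", "C2"), ("E3", "C3")):
            assert dy[STATE_NAMES.index(e)] + dy[STATE_NAMES.index(c)] == pytest.approx(0.0, abs=1e-12)

    def test_constant_density_removes_dilution_term(self, params):
        cond = CultureConditions(growth_rate=0.0)
        y = build_initial_state(params, cond)
        y[STATE_NAMES.index("U")] = 50.0  # would matter only through dN/dt
        dy = rhs(200.0, y, params, cond)
        dU = dy[STATE_NAMES.index("U")]
        expected = -cond.N0 * dU * cond.amount_to_conc / cond.V_c
        assert dy[STATE_NAMES.index("S1")] == pytest.approx(expected)

    def test_analytic_jacobians_match_numeric(self, params, conditions):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(1.0, 0.5, N_STATE_VARIABLES)) * np.array(
            [50, 10, 5, 20, 0.2, 0.08, 0.07, 0.05, 0.02, 0.02, 30]
        )
        t = 130.0
        J = jac_state(t, y, params, conditions)
        h = 1e-7
        for k in range(N_STATE_VARIABLES):
            dy = np.zeros(N_STATE_VARIABLES)
            dy[k] = h * max(1.0, abs(y[k]))
            num = (rhs(t, y + dy, params, conditions) - rhs(t, y - dy, params, conditions)) / (2 * dy[k])
            assert np.allclose(J[:, k], num, rtol=1e-5, atol=1e-8)
        Jp = jac_params(t, y, params, conditions)
        theta = params.theta()
        for k, name in enumerate(sidyn.PARAM_NAMES):
            h_k = 1e-7 * theta[k]
            up = replace(params, **{name: theta[k] + h_k})
            dn = replace(params, **{name: theta[k] - h_k})
            num = (rhs(t, y, up, conditions) - rhs(t, y, dn, conditions)) / (2 * h_k)
            assert np.allclose(Jp[:, k], num, rtol=1e-5, atol=1e-8), name


class TestSimulate:
    def test_no_transporters_leaves_medium_untouched(self, conditions):
        p = KineticParameters(E10=1e-300, E20=1e-300, E30=1e-300)
        traj = simulate(p, conditions)
        assert np.allclose(traj["S1"], conditions.S1_0, rtol=1e-12)

    def test_matches_fixed_step_reference_integrator(self, params, conditions, default_trajectory):
        t_grid = np.linspace(0.0, 300.0, 16)
        traj = simulate(params, conditions, t_grid=t_grid)
        ref = rk4_trajectory(params, conditions, traj.flux, t_grid, dt=0.01)
        scale = np.max(np.abs(ref), axis=0)
        scale[scale == 0] = 1.0
        assert np.max(np.abs(traj.states - ref) / scale) < 1e-4

    def test_enzyme_conservation_with_constant_totals(self, default_trajectory, params):
        _, enzyme = conservation_residuals(default_trajectory)
        assert enzyme.values.max() <= 1e-6

    def test_silicon_conservation(self, default_trajectory):
        silicon, _ = conservation_residuals(default_trajectory)
        assert silicon.max() <= 1e-6

    def test_non_negativity_along_default_trajectory(self, default_trajectory):
        atol = default_trajectory.diagnostics["atol"]
        assert default_trajectory.states.min() >= -10 * atol

    def test_tighter_tolerances_reduce_conservation_residual(self, params, conditions):
        loose = simulate(params, conditions, rtol=1e-6, atol=1e-8)
        tight = simulate(params, conditions, rtol=1e-10, atol=1e-12)
        s_loose, _ = conservation_residuals(loose)
        s_tight, _ = conservation_residuals(tight)
        assert s_tight.max() <= s_loose.max() + 1e-14

    def test_deterministic_for_fixed_inputs(self, params, conditions, default_trajectory):
        again = simulate(params, conditions)
        assert np.array_equal(again.states, default_trajectory.states)

    def test_first_state_is_initial_state(self, default_trajectory, params, conditions):
        y0 = build_initial_state(params, conditions)
        assert np.allclose(default_trajectory.states[0], y0, rtol=0, atol=1e-12)

    def test_invalid_grid_rejected(self, params, conditions):
        with pytest.raises(ValueError):
            simulate(params, conditions, t_grid=np.array([10.0, 20.0]))

    def test_sit_flux_preserves_scaled_enzyme_totals(self, params, conditions):
        profile = sidyn.default_sit_profile()
        traj = simulate(params, conditions, flux=profile)
        _, enzyme = conservation_residuals(traj)
        assert enzyme.values.max() <= 1e-6
        # with the dip active, the step-1 total at 150 min is half the initial
        k = np.argmin(np.abs(traj.times - 150.0))
        total = traj["E1"][k] + traj["C1"][k]
        assert total == pytest.approx(0.5 * params.E10, rel=1e-6)


class TestStateSpaceStructure:
    def test_conservation_law_matrix_rank_is_three(self):
        assert np.linalg.matrix_rank(conservation_law_matrix()) == 3

    def test_seven_independent_species_and_eleven_integrated_variables(self):
        assert n_independent_species() == 7
        assert N_STATE_VARIABLES == 11

    def test_laws_annihilate_the_stoichiometry(self):
        laws = conservation_law_matrix()
        S_full = np.vstack([np.zeros((1, 6)), sidyn.stoichiometric_matrix()])
        assert np.allclose(laws @ S_full, 0.0, atol=1e-12)
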