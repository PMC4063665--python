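import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sidyn import (
    FAILURE_SENTINEL,
    KineticParameters,
    Objective,
    ObjectiveConfig,
    ObservedDataset,
    SearchOptions,
    SearchSpace,
    acceptance_set,
    penalty,
    scatter_search,
    weighted_least_squares,
)


class TestWeightedLeastSquares:
    def test_perfect_fit_on_noise_free_data(self, params, conditions, noise_free_dataset):
        wls = weighted_least_squares(params, noise_free_dataset, conditions)
        assert wls < 1e-8

    def test_one_sigma_residual_per_point_counts_the_points(self, params, conditions, noise_free_dataset):
        # shift every fitted observation by exactly one sd: objective = n points
        records = noise_free_dataset.records.copy()
        fitted = records["quantity"].isin(["medium_Si", "final_silica"])
        records.loc[fitted, "value"] += records.loc[fitted, "sd"]
        shifted = ObservedDataset(records=records)
        wls = weighted_least_squares(params, shifted, conditions)
        assert wls == pytest.approx(shifted.n_fitted, rel=1e-6)

    def test_doubling_sds_quarters_the_value(self, params, conditions, noisy_dataset):
        wls1 = weighted_least_squares(params, noisy_dataset, conditions)
        records = noisy_dataset.records.copy()
        records["sd"] *= 2.0
        wls2 = weighted_least_squares(params, ObservedDataset(records=records), conditions)
        assert wls2 == pytest.approx(wls1 / 4.0, rel=1e-9)

    def test_unsimulatable_parameters_return_sentinel(self, conditions, noisy_dataset):
        # absurdly stiff corner that the solver rejects is reported, not raised
        theta = np.array([1e-12, 1e-12, 1e-12, 1e12, 1e12, 1e12, 1e6, 1e6, 1e6])
        val = weighted_least_squares(theta, noisy_dataset, conditions)
        assert val <= FAILURE_SENTINEL


class TestPenalty:
    def test_far_feasible_is_negligible(self):
        cfg = ObjectiveConfig()
        p = KineticParameters()
        rho = p.E0 / (1e-6 * cfg.epsilon)  # E0/rho = 1e-6 * epsilon
        assert penalty(p, rho, cfg) < 1e-3 * cfg.w

    def test_deep_violation_saturates_at_three_w(self):
        cfg = ObjectiveConfig()
        p = KineticParameters()
        rho = p.E0 / (1e3 * cfg.epsilon)
        assert abs(penalty(p, rho, cfg) - 3 * cfg.w) < 1e-3 * cfg.w

    def test_boundary_value_is_half_w_per_step(self):
        cfg = ObjectiveConfig()
        p = KineticParameters()
        rho = p.E0 / cfg.epsilon
        assert penalty(p, rho, cfg) == pytest.approx(1.5 * cfg.w, rel=1e-9)

    @given(scale=st.floats(1.0, 1e4), step=st.floats(1.0, 10.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_along_rays_of_increasing_enzyme(self, scale, step):
        cfg = ObjectiveConfig()
        rho = np.array([100.0, 30.0, 50.0])
        base = KineticParameters()
        p1 = KineticParameters(E10=base.E10 * scale, E20=base.E20 * scale, E30=base.E30 * scale)
        p2 = KineticParameters(
            E10=base.E10 * scale * step, E20=base.E20 * scale * step, E30=base.E30 * scale * step
        )
        assert penalty(p2, rho, cfg) >= penalty(p1, rho, cfg) - 1e-12

    def test_empty_pool_is_maximal_violation(self):
        cfg = ObjectiveConfig()
        p = KineticParameters()
        assert penalty(p, [0.0, 0.0, 0.0], cfg) == pytest.approx(3 * cfg.w)


class TestObjective:
    def test_feasible_truth_on_its_own_noise_free_data_is_small(self, noise_free_objective, params):
        wls, pen = noise_free_objective.components(params)
        assert wls < 1e-8
        assert pen < 0.02 * noise_free_objective.config.w

    def test_inflated_enzyme_totals_exceed_the_weight(self, noise_free_objective, params):
        inflated = KineticParameters(
            E10=params.E10 * 1e5, E20=params.E20 * 1e5, E30=params.E30 * 1e5
        )
        val = noise_free_objective(inflated)
        assert val > noise_free_objective.config.w

    def test_default_f_tol_is_data_count_plus_five(self, noise_free_objective):
        assert noise_free_objective.default_f_tol() == 11 + 5


class TestAcceptanceSet:
    def test_tolerance_below_minimum_gives_empty_set(self):
        thetas = np.ones((5, 9))
        fs = np.linspace(1.0, 2.0, 5)
        kept, _ = acceptance_set((thetas, fs), 0.5)
        assert len(kept) == 0

    def test_infinite_tolerance_keeps_all_distinct_points(self):
        rng = np.random.default_rng(0)
        thetas = rng.uniform(1.0, 2.0, (20, 9))
        fs = rng.uniform(0, 5, 20)
        kept, kept_f = acceptance_set((thetas, fs), np.inf)
        assert len(kept) == 20
        assert np.all(np.diff(kept_f) >= 0)

    def test_near_duplicates_are_merged(self):
        theta = np.ones(9)
        thetas = np.stack([theta, theta * (1 + 1e-9), theta * 2])
        fs = np.array([1.0, 2.0, 3.0])
        kept, kept_f = acceptance_set((thetas, fs), 10.0)
        assert len(kept) == 2
        assert kept_f[0] == 1.0  # duplicate kept its best objective


class TestSearchSpace:
    def test_unit_cube_round_trip(self):
        sp = SearchSpace()
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 1, sp.dim)
        assert np.allclose(sp.to_unit(sp.from_unit(z)), z)
        assert sp.contains(sp.from_unit(z))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=(1.0,) * 9, upper=(1.0,) * 9)
        with pytest.raises(ValueError):
            SearchSpace(lower=(-1.0,) + (0.5,) * 8)
        with pytest.raises(ValueError):
            SearchSpace(names=("a", "b"), lower=(0.1, 0.1), upper=(1.0, 1.0),
                        log_scale=(True, True))  # 'vmax' needs the 9 model coords


class TestScatterSearch:
    def test_convex_bowl_minimum_found(self):
        # 5-dim quadratic bowl with known minimizer
        target = np.array([3.0, 1.0, 2.0, 0.5, 4.0])
        space = SearchSpace(
            names=tuple("abcde"),
            lower=(0.1,) * 5,
            upper=(10.0,) * 5,
            log_scale=(False,) * 5,
            parameterization="direct",
        )
        fn = lambda x: float(np.sum((np.asarray(x) - target) ** 2))
        opts = SearchOptions(n_div=40, refset_size=8, max_evals=4000, local_budget=400,
                             polish_budget=2000, n_stall=5, f_tol=1e-12)
        res = scatter_search(fn, space, opts, seed=0)
        assert np.allclose(res.best_theta, target, atol=1e-3)

    def test_multimodal_matches_dense_random_search(self):
        # 2-dim Himmelblau-style surface: compare with a large random sample
        def fn(x):
            a, b = x
            return float((a * a + b - 11) ** 2 + (a + b * b - 7) ** 2)

        space = SearchSpace(
            names=("x", "y"), lower=(-6.0, -6.0), upper=(6.0, 6.0),
            log_scale=(False, False), parameterization="direct",
        )
        rng = np.random.default_rng(42)
        samples = rng.uniform(-6, 6, (100_000, 2))
        oracle = min(fn(s) for s in samples)
        opts = SearchOptions(n_div=30, refset_size=6, max_evals=1500, local_budget=200,
                             polish_budget=600, n_stall=4, f_tol=1e-10)
        res = scatter_search(fn, space, opts, seed=1)
        assert res.best_objective <= oracle + 1e-6

    def test_seeded_determinism(self):
        fn = lambda x: float(np.sum((np.log(np.asarray(x))) ** 2))
        space = SearchSpace(names=("a", "b"), lower=(0.1, 0.1), upper=(10.0, 10.0),
                            log_scale=(True, True), parameterization="direct")
        opts = SearchOptions(n_div=20, refset_size=6, max_evals=300, local_budget=50,
                             polish_budget=100, n_stall=3, f_tol=1e-10)
        r1 = scatter_search(fn, space, opts, seed=9)
        r2 = scatter_search(fn, space, opts, seed=9)
        assert np.array_equal(r1.thetas, r2.thetas)
        assert np.array_equal(r1.objectives, r2.objectives)
        assert r1.best_objective == r2.best_objective

    def test_stop_reason_reports_budget_exhaustion(self):
        fn = lambda x: float(np.sum(np.asarray(x) ** 2))
        space = SearchSpace(names=("a", "b"), lower=(-1.0, -1.0), upper=(1.0, 1.0),
                            log_scale=(False, False), parameterization="direct")
        opts = SearchOptions(n_div=10, refset_size=4, max_evals=30, local_budget=5,
                             polish_budget=0, n_stall=100, f_tol=-1.0)
        res = scatter_search(fn, space, opts, seed=0)
        assert res.stop_reason == "evaluation budget exhausted"
        assert res.n_evaluations <= 30 + 10
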