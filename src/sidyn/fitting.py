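"""Penalty-augmented weighted least squares and scatter-search estimation.

The objective is

    F(theta) = sum_i ((d_i - f_i(theta)) / sigma_i)^2  +  P(theta)

where the data term runs over the medium-silicon time series and the single
deposited-silica end point, and P is a smooth penalty enforcing the enzyme-
kinetics prior that total enzyme is much smaller than the substrate+product
pool it works on.  Fits below the data-error-based tolerance F_tol are all
equally acceptable (the acceptance interval); refining further would only fit
the noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .model import simulate
from .params import PARAM_NAMES, CultureConditions, KineticParameters, cell_density_curve, sit_flux
from .synthetic import ObservedDataset

#: Objective value recorded when the forward simulation fails for a trial theta.
FAILURE_SENTINEL = 1.0e6


@dataclass(frozen=True)
class ObjectiveConfig:
    """Tuning of the penalty term and the acceptance tolerance.

    * ``w`` — penalty weight; sized so one violated constraint contributes on
      the order of the data term (~ the number of data points).
    * ``alpha`` — steepness of the logistic switch (dimensionless, default 5;
      kept small so the constraint stays soft).
    * ``epsilon`` — the allowed ratio of total enzyme to the time-averaged
      substrate+product pool of its step.
    * ``f_tol`` — acceptance tolerance; ``None`` means n_fitted + 5 at fit time.
    """

    w: float = 10.0
    alpha: float = 5.0
    epsilon: float = 0.01
    f_tol: float | None = None
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        if self.w < 0 or self.alpha <= 0 or self.epsilon <= 0:
            raise ValueError("w must be >= 0; alpha, epsilon must be positive")
        if self.f_tol is not None and self.f_tol <= 0:
            raise ValueError("f_tol must be positive")


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter box bounds with optional log-scale search coordinates.

    The default space searches the kinetic model in its observable
    Michaelis-Menten coordinates (K_i, Vmax_i, E_i0) rather than directly in
    the turnover rates: the data term of the objective is governed almost
    entirely by (K_i, Vmax_i) while the enzyme-excess penalty acts on E_i0
    alone, so these coordinates decouple the two terms and remove the long
    kcat*E0-compensating valley from the search landscape.  Candidate vectors
    are always handed to the objective as the canonical parameter vector
    (kcat_i = Vmax_i / E_i0).  Set ``parameterization='direct'`` for a plain
    box over arbitrary coordinates.
    """

    names: tuple = ("K1", "K2", "K3", "Vmax1", "Vmax2", "Vmax3", "E10", "E20", "E30")
    lower: tuple = (0.5, 0.5, 0.1, 0.01, 0.01, 0.01, 1e-3, 1e-3, 1e-3)
    upper: tuple = (50.0, 50.0, 20.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0)
    log_scale: tuple = (True,) * 9
    parameterization: str = "vmax"

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if not (len(lo) == len(hi) == len(self.names) == len(self.log_scale)):
            raise ValueError("bounds, names and log flags must have equal length")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be below upper bounds")
        if any(f and l <= 0 for f, l in zip(self.log_scale, lo)):
            raise ValueError("log-scale parameters need positive lower bounds")
        if self.parameterization not in ("vmax", "direct"):
            raise ValueError("parameterization must be 'vmax' or 'direct'")
        if self.parameterization == "vmax" and len(self.names) != 9:
            raise ValueError("'vmax' parameterization requires the 9 model coordinates")

    @property
    def dim(self) -> int:
        return len(self.names)

    def coords_to_theta(self, coords: np.ndarray) -> np.ndarray:
        """Search coordinates -> canonical parameter vector (PARAM_NAMES order)."""
        coords = np.asarray(coords, float)
        if self.parameterization == "direct":
            return coords
        K, vmax, E0 = coords[0:3], coords[3:6], coords[6:9]
        return np.concatenate([K, vmax / E0, E0])

    def theta_to_coords(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        if self.parameterization == "direct":
            return theta
        K, kcat, E0 = theta[0:3], theta[3:6], theta[6:9]
        return np.concatenate([K, kcat * E0, E0])

    def _coords(self):
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        log = np.asarray(self.log_scale, bool)
        with np.errstate(invalid="ignore"):
            a = np.where(log, np.log(np.where(log, lo, 1.0)), lo)
            b = np.where(log, np.log(np.where(log, hi, 1.0)), hi)
        return a, b, log

    def from_unit(self, z: np.ndarray) -> np.ndarray:
        """Map unit-cube coordinates to a canonical parameter vector."""
        a, b, log = self._coords()
        x = a + np.asarray(z, float) * (b - a)
        return self.coords_to_theta(np.where(log, np.exp(x), x))

    def to_unit(self, theta: np.ndarray) -> np.ndarray:
        coords = self.theta_to_coords(theta)
        a, b, log = self._coords()
        x = np.where(log, np.log(coords), coords)
        return (x - a) / (b - a)

    def contains(self, theta: np.ndarray) -> bool:
        z = self.to_unit(theta)
        return bool(np.all(z >= -1e-12) and np.all(z <= 1 + 1e-12))


@dataclass(frozen=True)
class SearchOptions:
    """Budget and schedule of the scatter search."""

    n_div: int = 90          # diversification sample size
    refset_size: int = 10    # quality half + diversity half
    trials_per_pair: int = 2
    n_stall: int = 6         # stop after this many non-improving iterations
    max_evals: int = 12000
    local_budget: int = 500  # simplex evaluations per local refinement
    polish_budget: int = 6000
    f_tol: float = 1e-3      # stop refining below this (acceptance contract)


@dataclass
class FitResult:
    """Best parameters plus the accepted ensemble and the evaluation log."""

    best_theta: np.ndarray
    best_objective: float
    thetas: np.ndarray       # all evaluated parameter vectors
    objectives: np.ndarray
    n_evaluations: int
    seed: int
    stop_reason: str
    f_tol: float

    @property
    def best_params(self) -> KineticParameters:
        return KineticParameters.from_theta(self.best_theta)

    def ensemble(self, f_tol: float | None = None):
        tol = self.f_tol if f_tol is None else f_tol
        return acceptance_set((self.thetas, self.objectives), tol)


class Objective:
    """Callable objective F(theta) = weighted least squares + penalty.

    One forward simulation per evaluation serves both terms.  A failed
    simulation returns a large finite sentinel so a metaheuristic can keep
    searching.
    """

    def __init__(
        self,
        dataset: ObservedDataset,
        conditions: CultureConditions,
        flux=None,
        config: ObjectiveConfig | None = None,
        rev_ratio: float = 1.0,
    ):
        self.dataset = dataset
        self.conditions = conditions
        self.flux = sit_flux(flux)
        self.config = config if config is not None else ObjectiveConfig()
        self.rev_ratio = rev_ratio

        s1 = dataset.subset("medium_Si")
        fin = dataset.subset("final_silica")
        self._t_s1 = s1["time_min"].to_numpy(float)
        self._d_s1 = s1["value"].to_numpy(float)
        self._sd_s1 = s1["sd"].to_numpy(float)
        self._t_fin = float(fin["time_min"].iloc[0])
        self._d_fin = float(fin["value"].iloc[0])
        self._sd_fin = float(fin["sd"].iloc[0])
        self._t_grid = np.unique(
            np.concatenate([[0.0], self._t_s1, [self._t_fin], [conditions.t_end]])
        )

    def _simulate(self, params: KineticParameters):
        return simulate(
            params,
            self.conditions,
            self.flux,
            t_grid=self._t_grid,
            rtol=self.config.rtol,
            atol=self.config.atol,
        )

    def _wls_from_traj(self, traj, quantities=("medium_Si", "final_silica")) -> float:
        total = 0.0
        if "medium_Si" in quantities:
            res = (self._d_s1 - traj.interp("S1", self._t_s1)) / self._sd_s1
            total += float(res @ res)
        if "final_silica" in quantities:
            total += float(((self._d_fin - traj.interp("S4", self._t_fin)) / self._sd_fin) ** 2)
        return total

    def _rho_from_traj(self, traj) -> np.ndarray:
        """Time-averaged substrate+product pool for each step (fmol/cell)."""
        cond = self.conditions
        N, _ = cell_density_curve(traj.times, cond.N0, cond.t_lag, cond.growth_rate)
        per_cell_medium = traj["S1"] * cond.V_c / (cond.amount_to_conc * N)
        pools = np.array(
            [
                np.trapezoid(per_cell_medium + traj["S2"], traj.times),
                np.trapezoid(traj["S2"] + traj["S3"], traj.times),
                np.trapezoid(traj["S3"] + traj["S4"], traj.times),
            ]
        )
        return pools / (traj.times[-1] - traj.times[0])

    def _penalty_from_rho(self, params: KineticParameters, rho: np.ndarray) -> float:
        cfg = self.config
        terms = []
        for E0_i, rho_i in zip(params.E0, rho):
            if rho_i <= 0:
                terms.append(1.0)  # empty pool: maximal violation
                continue
            ratio = E0_i / rho_i
            terms.append(float(expit(cfg.alpha * np.log(ratio / cfg.epsilon))))
        return cfg.w * float(np.sum(terms))

    def components(self, theta) -> tuple[float, float]:
        """(weighted least squares, penalty) at theta; sentinel split on failure."""
        params = self._as_params(theta)
        try:
            traj = self._simulate(params)
        except RuntimeError:
            return FAILURE_SENTINEL, 0.0
        return self._wls_from_traj(traj), self._penalty_from_rho(params, self._rho_from_traj(traj))

    def _as_params(self, theta) -> KineticParameters:
        if isinstance(theta, KineticParameters):
            return theta
        return KineticParameters.from_theta(theta, rev_ratio=self.rev_ratio)

    def __call__(self, theta) -> float:
        wls, pen = self.components(theta)
        return wls + pen

    def default_f_tol(self) -> float:
        if self.config.f_tol is not None:
            return self.config.f_tol
        return self.dataset.n_fitted + 5.0


def weighted_least_squares(
    theta,
    dataset: ObservedDataset,
    conditions: CultureConditions,
    flux=None,
    config: ObjectiveConfig | None = None,
    quantities=("medium_Si", "final_silica"),
) -> float:
    """Data term of the objective: sum of squared sigma-weighted residuals."""
    obj = Objective(dataset, conditions, flux, config)
    params = obj._as_params(theta)
    try:
        traj = obj._simulate(params)
    except RuntimeError:
        return FAILURE_SENTINEL
    return obj._wls_from_traj(traj, quantities=quantities)


def penalty(
    theta,
    rho,
    config: ObjectiveConfig | None = None,
) -> float:
    """Enzyme-excess penalty given per-step substrate+product averages ``rho``.

    Each step contributes ``w * logistic(alpha * ln(r_i / epsilon))`` with
    ``r_i = E_i0 / rho_i``: ~0 deep inside the feasible region, w/2 at the
    boundary, saturating at w per step (3w total) deep in violation, smooth
    and monotone in every ``E_i0``.
    """
    config = config if config is not None else ObjectiveConfig()
    params = theta if isinstance(theta, KineticParameters) else KineticParameters.from_theta(theta)
    rho = np.asarray(rho, dtype=float)
    terms = []
    for E0_i, rho_i in zip(params.E0, rho):
        if rho_i <= 0:
            terms.append(1.0)
            continue
        terms.append(float(expit(config.alpha * np.log(E0_i / rho_i / config.epsilon))))
    return config.w * float(np.sum(terms))


def objective(
    theta,
    dataset: ObservedDataset,
    conditions: CultureConditions,
    flux=None,
    config: ObjectiveConfig | None = None,
) -> float:
    """Full objective (data term + penalty) for a single parameter vector."""
    return Objective(dataset, conditions, flux, config)(theta)


def acceptance_set(evaluations, f_tol: float):
    """All evaluated parameter vectors with objective <= f_tol, deduplicated.

    ``evaluations`` is ``(thetas, objectives)``; duplicates closer than 1e-6
    relative distance keep their best-objective representative.  Returns
    ``(thetas, objectives)`` sorted by objective; both empty if nothing passes.
    """
    thetas, objectives = evaluations
    thetas = np.asarray(thetas, float)
    objectives = np.asarray(objectives, float)
    mask = objectives <= f_tol
    thetas, objectives = thetas[mask], objectives[mask]
    order = np.argsort(objectives)
    thetas, objectives = thetas[order], objectives[order]
    kept_idx: list[int] = []
    for i in range(len(thetas)):
        dup = False
        for j in kept_idx:
            ref = np.linalg.norm(thetas[j])
            if ref > 0 and np.linalg.norm(thetas[i] - thetas[j]) / ref < 1e-6:
                dup = True
                break
        if not dup:
            kept_idx.append(i)
    return thetas[kept_idx], objectives[kept_idx]


def _latin_hypercube(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Stratified per-dimension (Latin hypercube) sample in the unit cube."""
    cells = (np.array([rng.permutation(n) for _ in range(d)]).T + rng.uniform(0, 1, (n, d))) / n
    return cells


def _maxmin_select(candidates: np.ndarray, anchors: np.ndarray, k: int) -> list[int]:
    """Greedy max-min-distance selection of k candidate indices."""
    chosen: list[int] = []
    if len(candidates) == 0:
        return chosen
    dists = np.min(
        np.linalg.norm(candidates[:, None, :] - anchors[None, :, :], axis=2), axis=1
    )
    for _ in range(min(k, len(candidates))):
        i = int(np.argmax(dists))
        chosen.append(i)
        d_new = np.linalg.norm(candidates - candidates[i], axis=1)
        dists = np.minimum(dists, d_new)
        dists[i] = -np.inf
    return chosen


def scatter_search(
    objective_fn,
    space: SearchSpace,
    options: SearchOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Population-based global search with local simplex refinement.

    Classic scatter-search skeleton: (1) a stratified diversification sample;
    (2) a reference set holding a quality half and a max-min-distance
    diversity half; (3) trial points generated along the segments spanned by
    reference pairs (with extrapolation); (4) derivative-free local refinement
    of improving trials, clipped to the box; (5) reference-set update.  Stops
    once the best objective reaches ``options.f_tol`` (further refinement
    would overfit the data), after ``n_stall`` non-improving iterations, or on
    budget exhaustion.  Deterministic for a fixed seed.
    """
    options = options if options is not None else SearchOptions()
    rng = np.random.default_rng(seed)
    d = space.dim

    log_thetas: list[np.ndarray] = []
    log_f: list[float] = []

    def evaluate(z: np.ndarray) -> float:
        z = np.clip(z, 0.0, 1.0)
        theta = space.from_unit(z)
        f = float(objective_fn(theta))
        log_thetas.append(theta)
        log_f.append(f)
        return f

    # 1. diversification
    Z = _latin_hypercube(rng, options.n_div, d)
    F = np.array([evaluate(z) for z in Z])

    # 2. initial reference set: quality half + diversity half
    b = options.refset_size
    b_q = b // 2
    order = np.argsort(F)
    ref_z = [Z[i] for i in order[:b_q]]
    ref_f = [F[i] for i in order[:b_q]]
    rest = order[b_q:]
    div_idx = _maxmin_select(Z[rest], np.array(ref_z), b - b_q)
    for i in div_idx:
        ref_z.append(Z[rest][i])
        ref_f.append(F[rest][i])

    best = int(np.argmin(ref_f))
    best_f, best_z = ref_f[best], ref_z[best].copy()
    stop_reason = "stalled"
    stall = 0

    def local_refine(z0: np.ndarray, budget: int) -> tuple[np.ndarray, float]:
        res = minimize(
            evaluate,
            np.clip(z0, 0.0, 1.0),
            method="Nelder-Mead",
            options={"maxfev": budget, "xatol": 1e-10, "fatol": 1e-12, "adaptive": True},
        )
        return np.clip(res.x, 0.0, 1.0), float(res.fun)

    while True:
        if best_f <= options.f_tol:
            stop_reason = "f_tol reached"
            break
        if len(log_f) >= options.max_evals:
            stop_reason = "evaluation budget exhausted"
            break
        if stall >= options.n_stall:
            stop_reason = "stalled"
            break

        # 3. combine reference pairs into trial points
        trial_z, trial_f = [], []
        for i, j in itertools.combinations(range(len(ref_z)), 2):
            for _ in range(options.trials_per_pair):
                u = rng.uniform(-0.3, 1.3, d)
                z = np.clip(ref_z[i] + u * (ref_z[j] - ref_z[i]), 0.0, 1.0)
                trial_z.append(z)
                trial_f.append(evaluate(z))
            if len(log_f) >= options.max_evals:
                break
        if not trial_f:
            stop_reason = "evaluation budget exhausted"
            break

        improved = False
        k = int(np.argmin(trial_f))
        # 4. local refinement of the most promising trial
        if trial_f[k] < best_f * 1.05 + 1e-12 and len(log_f) < options.max_evals:
            z_loc, f_loc = local_refine(trial_z[k], options.local_budget)
            trial_z.append(z_loc)
            trial_f.append(f_loc)

        # 5. reference-set update: quality + diversity over union
        all_z = np.array(ref_z + trial_z)
        all_f = np.array(ref_f + trial_f)
        order = np.argsort(all_f)
        new_ref_z = [all_z[i] for i in order[:b_q]]
        new_ref_f = [all_f[i] for i in order[:b_q]]
        rest = order[b_q:]
        div_idx = _maxmin_select(all_z[rest], np.array(new_ref_z), b - b_q)
        for i in div_idx:
            new_ref_z.append(all_z[rest][i])
            new_ref_f.append(all_f[rest][i])
        ref_z, ref_f = new_ref_z, new_ref_f

        if ref_f[0] < best_f - 1e-12 * max(1.0, abs(best_f)):
            improved = True
            best_f, best_z = ref_f[0], ref_z[0].copy()
        stall = 0 if improved else stall + 1

    # final intensification unless the acceptance tolerance is already met:
    # chained simplex restarts (a fresh simplex escapes the degenerate shapes
    # the method collapses to in 9 dimensions)
    spent = 0
    while (
        best_f > options.f_tol
        and spent < options.polish_budget
        and len(log_f) < options.max_evals
    ):
        chunk = min(1000, options.polish_budget - spent, options.max_evals - len(log_f))
        z_pol, f_pol = local_refine(best_z, chunk)
        spent += chunk
        if f_pol < best_f - 1e-9 * max(1.0, abs(best_f)):
            best_z, best_f = z_pol, f_pol
            if best_f <= options.f_tol:
                stop_reason = "f_tol reached"
        else:
            break

    thetas = np.array(log_thetas)
    objectives = np.array(log_f)
    i_best = int(np.argmin(objectives))
    return FitResult(
        best_theta=thetas[i_best],
        best_objective=float(objectives[i_best]),
        thetas=thetas,
        objectives=objectives,
        n_evaluations=len(objectives),
        seed=seed,
        stop_reason=stop_reason,
        f_tol=options.f_tol,
    )


def fit_dataset(
    dataset: ObservedDataset,
    conditions: CultureConditions,
    flux=None,
    config: ObjectiveConfig | None = None,
    space: SearchSpace | None = None,
    options: SearchOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Convenience wrapper: build the objective and run the scatter search.

    When no explicit stopping tolerance is configured the acceptance tolerance
    defaults to ``n_fitted + 5`` (the data-error-based criterion).
    """
    space = space if space is not None else SearchSpace()
    obj = Objective(dataset, conditions, flux, config)
    if options is None:
        options = SearchOptions(f_tol=obj.default_f_tol())
    result = scatter_search(obj, space, options, seed=seed)
    return result
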