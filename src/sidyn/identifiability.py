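"""Practical identifiability: forward sensitivities, perturbations, ensemble dispersion.

Raw sensitivities s_ij(t) = dx_i/dtheta_j are computed either by integrating
the forward sensitivity ODEs

    dS/dt = J_x(t, x) S + J_theta(t, x),      S(0) = dx0/dtheta

jointly with the state (analytic Jacobians of the mass-action right-hand
side), or by seeded central finite differences, which serves as an independent
oracle for the augmented system.  Normalized sensitivities
s_ij * theta_j / x_i are dimensionless and comparable across parameters;
entries where the state is numerically zero are masked, never zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fitting import Objective, ObjectiveConfig
from .model import N_STATE_VARIABLES, STATE_NAMES, build_initial_state, jac_params, jac_state, rhs, simulate
from .params import PARAM_NAMES, CultureConditions, KineticParameters, sit_flux
from .synthetic import ObservedDataset

#: Observables used in the fit (medium silicon and deposited silica).
DEFAULT_OBSERVABLES = ("S1", "S4")


@dataclass
class SensitivityResult:
    """Raw (and optionally normalized) trajectory sensitivities.

    ``sens`` has shape (n_times, n_states, n_params); ``normalized`` is a
    masked array of the same shape when computed.
    """

    times: np.ndarray
    states: np.ndarray            # (n_times, 11)
    sens: np.ndarray              # (n_times, 11, n_params)
    param_names: tuple
    method: str
    normalized: np.ma.MaskedArray | None = None

    def raw(self, state: str, param: str) -> np.ndarray:
        return self.sens[:, STATE_NAMES.index(state), self.param_names.index(param)]

    def normed(self, state: str, param: str) -> np.ma.MaskedArray:
        if self.normalized is None:
            raise ValueError("normalized sensitivities not computed yet")
        return self.normalized[:, STATE_NAMES.index(state), self.param_names.index(param)]

    def to_long_frame(self, observables=DEFAULT_OBSERVABLES) -> pd.DataFrame:
        rows = []
        which = self.normalized if self.normalized is not None else self.sens
        kind = "normalized" if self.normalized is not None else "raw"
        for s in observables:
            i = STATE_NAMES.index(s)
            for j, p in enumerate(self.param_names):
                for k, t in enumerate(self.times):
                    v = which[k, i, j]
                    masked = bool(np.ma.is_masked(v))
                    rows.append((s, p, float(t), np.nan if masked else float(v), masked))
        return pd.DataFrame(rows, columns=["observable", "parameter", "time_min", kind, "masked"])


def _theta_subset(which_params):
    if which_params is None:
        return tuple(PARAM_NAMES)
    unknown = set(which_params) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    return tuple(which_params)


def sensitivity_trajectories(
    params: KineticParameters,
    conditions: CultureConditions,
    flux=None,
    which_params=None,
    method: str = "augmented-ode",
    t_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SensitivityResult:
    """State sensitivities to the fitted parameters along the trajectory.

    ``method='augmented-ode'`` integrates state and sensitivities jointly;
    ``method='finite-difference'`` re-simulates at theta*(1 ± 1e-6) and takes
    central differences (the independent check).
    """
    which = _theta_subset(which_params)
    flux = sit_flux(flux)
    if t_grid is None:
        t_grid = np.linspace(0.0, conditions.t_end, 61)
    t_grid = np.asarray(t_grid, dtype=float)

    if method == "finite-difference":
        return _sensitivity_fd(params, conditions, flux, which, t_grid, rtol, atol)
    if method != "augmented-ode":
        raise ValueError("method must be 'augmented-ode' or 'finite-difference'")

    sel = [PARAM_NAMES.index(p) for p in which]
    n_p = len(sel)
    n = N_STATE_VARIABLES

    y0 = build_initial_state(params, conditions)
    S0 = np.zeros((n, n_p))
    for col, j in enumerate(sel):
        name = PARAM_NAMES[j]
        if name in ("E10", "E20", "E30"):
            # E_i(0) = E_i0: the initial condition depends on the parameter
            S0[STATE_NAMES.index("E" + name[1]), col] = 1.0
    aug0 = np.concatenate([y0, S0.ravel()])

    def aug_rhs(t, aug):
        y = aug[:n]
        S = aug[n:].reshape(n, n_p)
        J = jac_state(t, y, params, conditions, flux)
        Jp = jac_params(t, y, params, conditions, flux)[:, sel]
        dy = rhs(t, y, params, conditions, flux)
        dS = J @ S + Jp
        return np.concatenate([dy, dS.ravel()])

    sol = solve_ivp(
        aug_rhs,
        (0.0, float(t_grid[-1])),
        aug0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"augmented sensitivity integration failed: {sol.message}")
    states = sol.y[:n].T
    sens = sol.y[n:].T.reshape(len(t_grid), n, n_p)
    return SensitivityResult(
        times=t_grid, states=states, sens=sens, param_names=which, method="augmented-ode"
    )


def _sensitivity_fd(params, conditions, flux, which, t_grid, rtol, atol, rel_step=1e-6):
    base = simulate(params, conditions, flux, t_grid=t_grid, rtol=rtol, atol=atol)
    n_p = len(which)
    sens = np.zeros((len(t_grid), N_STATE_VARIABLES, n_p))
    for col, name in enumerate(which):
        theta0 = getattr(params, name)
        h = rel_step * theta0
        hi = simulate(
            _with_param(params, name, theta0 + h), conditions, flux, t_grid=t_grid,
            rtol=rtol, atol=atol,
        )
        lo = simulate(
            _with_param(params, name, theta0 - h), conditions, flux, t_grid=t_grid,
            rtol=rtol, atol=atol,
        )
        sens[:, :, col] = (hi.states - lo.states) / (2.0 * h)
    return SensitivityResult(
        times=t_grid, states=base.states, sens=sens, param_names=tuple(which),
        method="finite-difference",
    )


def _with_param(params: KineticParameters, name: str, value: float) -> KineticParameters:
    return replace(params, **{name: value})


def normalized_sensitivity(
    raw: SensitivityResult,
    params: KineticParameters,
    floor: float = 1e-12,
) -> SensitivityResult:
    """Scale raw sensitivities to s_ij * theta_j / x_i, masking tiny states.

    The result is dimensionless and invariant under parameter-unit rescaling;
    entries with |x_i| below ``floor`` are masked rather than regularized.
    """
    theta = np.array([getattr(params, p) for p in raw.param_names])
    x = raw.states[:, :, None]
    small = np.abs(x) < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        normed = raw.sens * theta[None, None, :] / np.where(small, np.nan, x)
    masked = np.ma.masked_invalid(np.where(np.broadcast_to(small, normed.shape), np.nan, normed))
    out = SensitivityResult(
        times=raw.times,
        states=raw.states,
        sens=raw.sens,
        param_names=raw.param_names,
        method=raw.method,
        normalized=masked,
    )
    return out


@dataclass
class PerturbationReport:
    """Effect of multiplicative parameter perturbations on fit and dynamics."""

    table: pd.DataFrame  # parameter, direction, objective_base, objective_perturbed,
                         # max_rel_dev_<obs>..., shape_preserved
    fraction: float


def perturbation_analysis(
    params: KineticParameters,
    dataset: ObservedDataset,
    conditions: CultureConditions,
    flux=None,
    fraction: float = 0.10,
    which_params=None,
    config: ObjectiveConfig | None = None,
    observables=DEFAULT_OBSERVABLES,
    t_grid=None,
) -> PerturbationReport:
    """Re-simulate with each parameter scaled by (1 ± fraction).

    Records the objective before/after, the maximum relative trajectory
    deviation per observable, and whether the qualitative shape (sign pattern
    of the time derivative) of each observable is preserved.  Simulation
    failures are recorded per parameter, not raised.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    which = _theta_subset(which_params)
    flux = sit_flux(flux)
    if t_grid is None:
        t_grid = np.linspace(0.0, conditions.t_end, 61)
    obj = Objective(dataset, conditions, flux, config)
    base_traj = simulate(params, conditions, flux, t_grid=t_grid)
    f_base = obj(params)

    rows = []
    for name in which:
        for sign, tag in ((+1.0, "up"), (-1.0, "down")):
            value = getattr(params, name) * (1.0 + sign * fraction)
            pert = _with_param(params, name, value)
            row: dict = {"parameter": name, "direction": tag, "objective_base": f_base}
            try:
                traj = simulate(pert, conditions, flux, t_grid=t_grid)
            except RuntimeError as err:
                row.update({"objective_perturbed": np.nan, "failed": str(err)})
                rows.append(row)
                continue
            row["objective_perturbed"] = obj(pert)
            preserved = True
            for s in observables:
                b, p = base_traj[s], traj[s]
                scale = np.max(np.abs(b))
                dev = 0.0 if scale == 0 else float(np.max(np.abs(p - b)) / scale)
                row[f"max_rel_dev_{s}"] = dev
                preserved = preserved and _shape_preserved(base_traj.times, b, p)
            row["shape_preserved"] = preserved
            row["failed"] = ""
            rows.append(row)
    return PerturbationReport(table=pd.DataFrame(rows), fraction=fraction)


def _shape_preserved(times, base, pert, tol_frac: float = 1e-3) -> bool:
    """Sign pattern of the time derivative agrees wherever it is decisive."""
    db, dp = np.diff(base), np.diff(pert)
    scale = np.max(np.abs(db))
    if scale == 0:
        return True
    decisive = (np.abs(db) > tol_frac * scale) & (np.abs(dp) > tol_frac * scale)
    return bool(np.all(np.sign(db[decisive]) == np.sign(dp[decisive])))


def scatter_dispersion(
    thetas: np.ndarray,
    space=None,
    param_names=PARAM_NAMES,
    cv_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-parameter dispersion of an accepted ensemble.

    Returns coefficient of variation, the range over the search-space bound
    range (log-scaled where the search was log-scaled), and a flag for
    parameters that remain scattered (practically non-identifiable).  When a
    search space is given, dispersion is reported in its search coordinates
    (and labelled with its names) so the table matches what was searched.
    """
    thetas = np.asarray(thetas, float)
    if thetas.ndim != 2 or len(thetas) == 0:
        raise ValueError("ensemble must be a non-empty (n, p) array")
    if len(thetas) == 1:
        warnings.warn("singleton ensemble: dispersion is trivially zero")
    if space is not None:
        thetas = np.array([space.theta_to_coords(th) for th in thetas])
        param_names = space.names
    mean = thetas.mean(axis=0)
    cv = np.where(mean != 0, thetas.std(axis=0) / np.abs(mean), 0.0)
    out = pd.DataFrame({"parameter": list(param_names), "cv": cv})
    if space is not None:
        ratios = []
        for j in range(thetas.shape[1]):
            lo, hi = space.lower[j], space.upper[j]
            if space.log_scale[j]:
                width = np.log(hi) - np.log(lo)
                r = (np.log(thetas[:, j].max()) - np.log(thetas[:, j].min())) / width
            else:
                r = (thetas[:, j].max() - thetas[:, j].min()) / (hi - lo)
            ratios.append(r)
        out["range_ratio"] = ratios
    out["scattered"] = out["cv"] > cv_threshold
    return out
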