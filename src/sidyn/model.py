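"""Single-cell enzymatic transport/deposition ODEs coupled to a shared medium.

Silicon crosses three enzymatic steps, each a reversible binding followed by
irreversible catalysis::

    S1 + E1 <-> C1 -> S2 + E1      (SIT uptake across the plasma membrane)
    S2 + E2 <-> C2 -> S3 + E2      (transport into the SDV)
    S3 + E3 <-> C3 -> S4 + E3      (silica deposition inside the SDV)

S1 is the medium silicic-acid concentration shared by the whole culture; S2-S4
and the enzyme species are per-cell amounts.  The medium couples to the
population through the mass balance

    dS1/dt = -(1/V_c) [ N(t) dU/dt + U dN/dt ]

where U is the cumulative net per-cell uptake: the first term is uptake by the
synchronized majority, the second accounts for early-dividing cells entering
the consuming population.  Eleven variables are integrated
(S1, S2, S3, S4, E1, E2, E3, C1, C2, C3, U).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .params import (
    CultureConditions,
    KineticParameters,
    SITFluxProfile,
    cell_density_curve,
    sit_flux,
)

STATE_NAMES = ("S1", "S2", "S3", "S4", "E1", "E2", "E3", "C1", "C2", "C3", "U")
#: Number of integrated variables (10 reaction species + cumulative uptake).
N_STATE_VARIABLES = len(STATE_NAMES)
#: The reaction species (everything except the bookkeeping variable U).
REACTION_SPECIES = STATE_NAMES[:10]

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def mm_rate(K: float, vmax: float, s) -> np.ndarray | float:
    """Michaelis-Menten rate ``vmax * s / (K + s)``.

    Monotone non-decreasing and bounded by ``vmax``; equals ``vmax/2`` at
    ``s = K``.  Raises ``ValueError`` for non-positive ``K``, negative
    ``vmax`` or negative substrate.
    """
    if K <= 0:
        raise ValueError(f"half-saturation K must be positive, got {K}")
    if vmax < 0:
        raise ValueError("vmax must be non-negative")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate level must be non-negative")
    out = vmax * s / (K + s)
    return float(out) if out.ndim == 0 else out


def build_initial_state(
    params: KineticParameters, conditions: CultureConditions
) -> np.ndarray:
    """State vector immediately after 24 h silicon starvation.

    All intracellular silicon pools and complexes are empty, every active site
    is free, and the medium carries the freshly added silicic acid.
    """
    y0 = np.zeros(N_STATE_VARIABLES)
    y0[_IDX["S1"]] = conditions.S1_0
    y0[_IDX["E1"]], y0[_IDX["E2"]], y0[_IDX["E3"]] = params.E0
    return y0


def rhs(t, y, params: KineticParameters, conditions: CultureConditions, flux=None):
    """Time derivative of the 11-variable state (mass action + population coupling)."""
    flux = sit_flux(flux)
    kf, kr, kcat, E0 = params.kf, params.kr, params.kcat, params.E0

    sub = y[0:3]          # S1, S2, S3
    E = y[4:7]
    C = y[7:10]
    U = y[10]

    gp = np.array([flux[i](t)[1] for i in range(3)])

    vb = kf * sub * E     # binding
    vu = kr * C           # unbinding
    vc = kcat * C         # catalysis

    dC = vb - vu - vc
    dE = -vb + vu + vc + E0 * gp
    dU = vb[0] - vu[0]

    dS2 = vc[0] - vb[1] + vu[1]
    dS3 = vc[1] - vb[2] + vu[2]
    dS4 = vc[2]

    N, dN = cell_density_curve(t, conditions.N0, conditions.t_lag, conditions.growth_rate)
    c = conditions.amount_to_conc / conditions.V_c
    dS1 = -c * (N * dU + U * dN)

    out = np.empty(N_STATE_VARIABLES)
    out[0] = dS1
    out[1], out[2], out[3] = dS2, dS3, dS4
    out[4:7] = dE
    out[7:10] = dC
    out[10] = dU
    return out


def jac_state(t, y, params: KineticParameters, conditions: CultureConditions, flux=None):
    """Analytic Jacobian d(rhs)/d(state), 11 x 11."""
    kf, kr, kcat = params.kf, params.kr, params.kcat
    S1, S2, S3 = y[0], y[1], y[2]
    E1, E2, E3 = y[4], y[5], y[6]

    J = np.zeros((N_STATE_VARIABLES, N_STATE_VARIABLES))

    # dU = kf1*S1*E1 - kr1*C1
    J[10, 0] = kf[0] * E1
    J[10, 4] = kf[0] * S1
    J[10, 7] = -kr[0]

    # dS1 = -c (N dU + U dN)
    N, dN = cell_density_curve(t, conditions.N0, conditions.t_lag, conditions.growth_rate)
    c = conditions.amount_to_conc / conditions.V_c
    J[0, :] = -c * N * J[10, :]
    J[0, 10] = -c * dN

    # step blocks: (substrate idx, enzyme idx, complex idx, product row)
    for i, (s_i, e_i, c_i, p_i) in enumerate(((0, 4, 7, 1), (1, 5, 8, 2), (2, 6, 9, 3))):
        s_val, e_val = y[s_i], y[e_i]
        # complex row
        J[c_i, s_i] += kf[i] * e_val
        J[c_i, e_i] += kf[i] * s_val
        J[c_i, c_i] += -(kr[i] + kcat[i])
        # free-enzyme row
        J[e_i, s_i] += -kf[i] * e_val
        J[e_i, e_i] += -kf[i] * s_val
        J[e_i, c_i] += kr[i] + kcat[i]
        # substrate row (medium handled above through the population equation)
        if s_i != 0:
            J[s_i, s_i] += -kf[i] * e_val
            J[s_i, e_i] += -kf[i] * s_val
            J[s_i, c_i] += kr[i]
        # product row gains kcat_i * C_i
        J[p_i, c_i] += kcat[i]
    return J


def jac_params(t, y, params: KineticParameters, conditions: CultureConditions, flux=None):
    """Analytic Jacobian d(rhs)/d(theta), 11 x 9, theta in PARAM_NAMES order."""
    flux = sit_flux(flux)
    kf, kr, kcat, K = params.kf, params.kr, params.kcat, params.K
    r = params.rev_ratio

    Jp = np.zeros((N_STATE_VARIABLES, 9))
    gp = np.array([flux[i](t)[1] for i in range(3)])

    for i, (s_i, e_i, c_i, p_i) in enumerate(((0, 4, 7, 1), (1, 5, 8, 2), (2, 6, 9, 3))):
        s_val, e_val, c_val = y[s_i], y[e_i], y[7 + i]
        vb = kf[i] * s_val * e_val
        iK, ikcat, iE0 = i, 3 + i, 6 + i

        # d vb / dK_i = -vb/K_i ; d vb / dkcat_i = (1+r)/K_i * s*E
        dvb_dK = -vb / K[i]
        dvb_dkcat = (1.0 + r) / K[i] * s_val * e_val
        dvu_dkcat = r * c_val
        dvc_dkcat = c_val

        # complex row: vb - vu - vc
        Jp[c_i, iK] += dvb_dK
        Jp[c_i, ikcat] += dvb_dkcat - dvu_dkcat - dvc_dkcat
        # enzyme row: -(vb - vu - vc) + E0_i * g_i'
        Jp[e_i, iK] += -dvb_dK
        Jp[e_i, ikcat] += -(dvb_dkcat - dvu_dkcat - dvc_dkcat)
        Jp[e_i, iE0] += gp[i]
        # substrate row: loses vb - vu
        if s_i != 0:
            Jp[s_i, iK] += -dvb_dK
            Jp[s_i, ikcat] += -(dvb_dkcat - dvu_dkcat)
        # product row: gains vc
        Jp[p_i, ikcat] += dvc_dkcat

    # dU = vb1 - vu1
    vb0 = kf[0] * y[0] * y[4]
    Jp[10, 0] = -vb0 / K[0]
    Jp[10, 3] = (1.0 + r) / K[0] * y[0] * y[4] - r * y[7]

    N, _ = cell_density_curve(t, conditions.N0, conditions.t_lag, conditions.growth_rate)
    c = conditions.amount_to_conc / conditions.V_c
    Jp[0, :] = -c * N * Jp[10, :]
    return Jp


@dataclass
class Trajectory:
    """Integrated model output on a time grid, with its generating inputs."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 11)
    params: KineticParameters
    conditions: CultureConditions
    flux: tuple
    diagnostics: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        return df

    def interp(self, name: str, t) -> np.ndarray | float:
        """Linear interpolation of one state variable at arbitrary times."""
        out = np.interp(t, self.times, self[name])
        return float(out) if np.ndim(t) == 0 else out


def simulate(
    params: KineticParameters,
    conditions: CultureConditions,
    flux=None,
    t_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from the post-starvation initial state.

    Uses a stiff-capable solver with the analytic state Jacobian.  Raises
    ``RuntimeError`` with the failing time on step-size collapse.
    """
    flux = sit_flux(flux)
    if t_grid is None:
        t_grid = np.linspace(0.0, conditions.t_end, 121)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")

    y0 = build_initial_state(params, conditions)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        jac=jac_state,
        args=(params, conditions, flux),
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"integration failed near t = {t_fail:.3f} min: {sol.message}")
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        params=params,
        conditions=conditions,
        flux=flux,
        diagnostics={"rtol": rtol, "atol": atol, "method": method, "nfev": sol.nfev},
    )


def conservation_residuals(traj: Trajectory, conditions: CultureConditions | None = None):
    """Relative drift of the conserved totals along a trajectory.

    Returns ``(silicon, enzyme)``: a Series of relative errors of the total
    silicon budget ``S1*V_c + N(t)*U`` (in µmol, per the population mass
    balance) and a DataFrame of ``|E_i + C_i - g_i(t) E_i0| / E_i0`` for each
    enzymatic step.
    """
    cond = conditions if conditions is not None else traj.conditions
    t = traj.times
    N, _ = cell_density_curve(t, cond.N0, cond.t_lag, cond.growth_rate)
    total = traj["S1"] * cond.V_c + cond.amount_to_conc * N * traj["U"]
    if total[0] == 0:
        raise ValueError("initial conserved silicon total is zero")
    silicon = pd.Series(np.abs(total - total[0]) / total[0], index=t, name="silicon_rel_err")

    enzyme = {}
    for i, (e, c) in enumerate((("E1", "C1"), ("E2", "C2"), ("E3", "C3"))):
        E0_i = traj.params.E0[i]
        if E0_i == 0:
            raise ValueError("enzyme total is zero; conservation undefined")
        g = np.array([traj.flux[i](tk)[0] for tk in t])
        enzyme[f"step{i + 1}"] = np.abs(traj[e] + traj[c] - g * E0_i) / E0_i
    enzyme = pd.DataFrame(enzyme, index=t)
    return silicon, enzyme


def stoichiometric_matrix() -> np.ndarray:
    """Stoichiometry of the per-cell reaction network, 9 species x 6 reactions.

    Species rows follow REACTION_SPECIES[1:] (S2..S4, E1..E3, C1..C3); the
    medium pool is an external reservoir here — it belongs to the population
    balance, not the per-cell network.  Columns are net binding and catalysis
    for each step.
    """
    species = REACTION_SPECIES[1:]
    idx = {s: i for i, s in enumerate(species)}
    S = np.zeros((len(species), 6))
    steps = (("S1", "E1", "C1", "S2"), ("S2", "E2", "C2", "S3"), ("S3", "E3", "C3", "S4"))
    for i, (sub, enz, cpx, prod) in enumerate(steps):
        b, c = 2 * i, 2 * i + 1
        if sub in idx:
            S[idx[sub], b] = -1
        S[idx[enz], b] = -1
        S[idx[cpx], b] = +1
        S[idx[cpx], c] = -1
        S[idx[enz], c] = +1
        S[idx[prod], c] = +1
    return S


def conservation_law_matrix() -> np.ndarray:
    """Conservation laws of the reaction network over the 10 reaction species.

    Computed as the left null space of the per-cell stoichiometric matrix and
    embedded over (S1, S2, S3, S4, E1, E2, E3, C1, C2, C3) with a zero medium
    coefficient: because the medium pool is shared by a growing population, no
    combination involving it is conserved per cell.  The surviving laws are the
    three enzyme totals E_i + C_i.
    """
    S = stoichiometric_matrix()
    ns = null_space(S.T)
    laws = np.hstack([np.zeros((ns.shape[1], 1)), ns.T])
    return laws


def n_independent_species() -> int:
    """Independent reaction species: 10 minus the rank of the conservation laws."""
    rank = np.linalg.matrix_rank(conservation_law_matrix())
    return len(REACTION_SPECIES) - rank
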