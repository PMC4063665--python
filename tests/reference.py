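"""Independent reference implementations used as test oracles.

Deliberately simple and separate from the package's solver paths: a classical
fixed-step RK4 integrator over the model right-hand side.
"""

import numpy as np

from sidyn.model import build_initial_state, rhs


def rk4_trajectory(params, conditions, flux, t_grid, dt=0.01):
    """Fixed-step RK4 integration reporting states at the points of t_grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    y = build_initial_state(params, conditions).astype(float)
    out = np.empty((len(t_grid), len(y)))
    t = 0.0
    k = 0
    if t_grid[0] == 0.0:
        out[0] = y
        k = 1
    t_final = t_grid[-1]
    while k < len(t_grid):
        t_next = t_grid[k]
        n_steps = max(1, int(np.ceil((t_next - t) / dt)))
        h = (t_next - t) / n_steps
        for _ in range(n_steps):
            k1 = rhs(t, y, params, conditions, flux)
            k2 = rhs(t + h / 2, y + h / 2 * k1, params, conditions, flux)
            k3 = rhs(t + h / 2, y + h / 2 * k2, params, conditions, flux)
            k4 = rhs(t + h, y + h * k3, params, conditions, flux)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[k] = y
        k += 1
    return out
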