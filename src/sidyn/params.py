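"""Parameter, condition and flux-profile containers for the silicon transport model.

Units used throughout the package:

* medium silicic-acid concentration — µmol/L (µM)
* per-cell silicon and enzyme amounts — fmol/cell
* time — minutes
* cell density — cells/L
* culture volume — L

The single unit conversion (fmol -> µmol, ``AMOUNT_TO_CONC``) lives here so the
dynamics code never carries unit factors of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: µmol per fmol: converts per-cell amounts to medium concentration units
#: (1 fmol = 1e-15 mol, 1 µmol = 1e-6 mol).
AMOUNT_TO_CONC = 1e-9

#: Canonical ordering of the fitted parameter vector.
PARAM_NAMES = ("K1", "K2", "K3", "kcat1", "kcat2", "kcat3", "E10", "E20", "E30")


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic constants of the three enzymatic transport/deposition steps.

    Step 1 moves silicic acid from the medium into the cytoplasm (SIT uptake),
    step 2 from the cytoplasm into the silica deposition vesicle (SDV), and
    step 3 deposits soluble SDV silicon as solid silica.  Each step is a
    reversible enzyme-substrate binding followed by irreversible catalysis,
    parameterized by the observable Michaelis-Menten constants: half-saturation
    ``K_i``, turnover ``kcat_i`` (1/min) and initial total active sites
    ``E_i0`` (fmol/cell).  ``K1`` is a medium concentration (µM); ``K2``/``K3``
    are per-cell amounts (fmol).

    The underlying mass-action constants are derived as

    * forward  ``kf_i = kcat_i (1 + rev_ratio) / K_i``
    * reverse  ``kr_i = rev_ratio * kcat_i``

    so that ``K_i = (kr_i + kcat_i) / kf_i`` is the Michaelis constant.
    ``rev_ratio`` (ratio of unbinding to catalytic rate) is fixed, not fitted.
    """

    K1: float = 8.0
    K2: float = 5.0
    K3: float = 2.0
    kcat1: float = 2.0
    kcat2: float = 5.0
    kcat3: float = 5.0
    E10: float = 0.25
    E20: float = 0.10
    E30: float = 0.09
    rev_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES + ("rev_ratio",):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def K(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.K3])

    @property
    def kcat(self) -> np.ndarray:
        return np.array([self.kcat1, self.kcat2, self.kcat3])

    @property
    def E0(self) -> np.ndarray:
        return np.array([self.E10, self.E20, self.E30])

    @property
    def kf(self) -> np.ndarray:
        """Forward (binding) rate constants, per substrate unit per minute."""
        return self.kcat * (1.0 + self.rev_ratio) / self.K

    @property
    def kr(self) -> np.ndarray:
        """Reverse (unbinding) rate constants, 1/min."""
        return self.rev_ratio * self.kcat

    @property
    def vmax(self) -> np.ndarray:
        """Maximum catalytic rates ``kcat_i * E_i0`` (fmol/cell/min)."""
        return self.kcat * self.E0

    def theta(self) -> np.ndarray:
        """The fitted parameter vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_theta(cls, theta: Sequence[float], rev_ratio: float = 1.0) -> "KineticParameters":
        values = dict(zip(PARAM_NAMES, map(float, theta)))
        return cls(rev_ratio=rev_ratio, **values)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CultureConditions:
    """Bulk-culture setup coupling single cells to the shared medium.

    The cell-density curve is flat at ``N0`` for ``t_lag`` minutes (silicon
    starvation synchronizes most of the population at a common arrest point)
    and then grows exponentially at ``growth_rate`` as the non-synchronized
    minority divides early.
    """

    V_c: float = 1.0            # culture volume, L
    N0: float = 5.0e8           # initial cell density, cells/L
    t_lag: float = 120.0        # flat-density interval, min
    growth_rate: float = 2.0e-3  # post-lag exponential rate, 1/min
    S1_0: float = 100.0         # initial medium silicic acid, µM
    t_end: float = 300.0        # observation horizon, min
    amount_to_conc: float = AMOUNT_TO_CONC

    def __post_init__(self) -> None:
        for name in ("V_c", "N0", "S1_0", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.t_lag <= self.t_end:
            raise ValueError("t_lag must lie within [0, t_end]")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SITFluxProfile:
    """Piecewise-linear relative expression level g(t) of one enzyme's total.

    ``knots`` is an ordered sequence of ``(time_min, multiplier)`` pairs;
    g interpolates linearly between knots and is constant outside their range.
    The enzyme-conservation law becomes ``E_i + C_i = g_i(t) * E_i0``, so a
    profile with g(0) = 1 leaves the initial totals untouched.
    """

    knots: tuple = ((0.0, 1.0),)

    def __post_init__(self) -> None:
        if len(self.knots) == 0:
            raise ValueError("SITFluxProfile requires at least one knot")
        times = np.array([k[0] for k in self.knots], dtype=float)
        values = np.array([k[1] for k in self.knots], dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(values <= 0):
            raise ValueError("knot multipliers must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([k[0] for k in self.knots], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([k[1] for k in self.knots], dtype=float)

    def __call__(self, t: float) -> tuple[float, float]:
        """Return ``(g(t), g'(t))``; the derivative is 0 outside the knot range.

        At a knot the right-hand derivative is reported.
        """
        times, values = self.times, self.values
        if len(times) == 1:
            return float(values[0]), 0.0
        g = float(np.interp(t, times, values))
        if t < times[0] or t >= times[-1]:
            return g, 0.0
        j = int(np.searchsorted(times, t, side="right")) - 1
        j = min(max(j, 0), len(times) - 2)
        slope = (values[j + 1] - values[j]) / (times[j + 1] - times[j])
        return g, float(slope)


def cell_density_curve(t, N0: float, t_lag: float, growth_rate: float):
    """Cell density N(t) and its exact derivative for a lag-then-growth culture.

    N = N0 for t <= t_lag, then N0*exp(growth_rate*(t - t_lag)); continuous at
    the lag point.  An analytic curve keeps dN/dt exact inside the medium
    equation (no numerical differentiation).

    Parameters are scalars; ``t`` may be a scalar or array (min).
    """
    if growth_rate < 0:
        raise ValueError("growth_rate must be non-negative")
    t = np.asarray(t, dtype=float)
    grown = t > t_lag
    N = np.where(grown, N0 * np.exp(growth_rate * (np.maximum(t - t_lag, 0.0))), N0)
    dN = np.where(grown, growth_rate * N, 0.0)
    if N.ndim == 0:
        return float(N), float(dN)
    return N, dN


def constant_flux() -> tuple[SITFluxProfile, SITFluxProfile, SITFluxProfile]:
    """Classical-kinetics case: all enzyme totals constant (g ≡ 1)."""
    p = SITFluxProfile()
    return (p, p, p)


def default_sit_profile() -> SITFluxProfile:
    """Default cell-cycle SIT expression profile.

    Starts at 1 (classical totals right after starvation release), dips to
    0.5 in the S-phase window (~120-180 min, when silica deposition pauses),
    and rises above 1 during valve formation, staying within ±50% of the
    average level.
    """
    return SITFluxProfile(
        knots=(
            (0.0, 1.0),
            (100.0, 0.9),
            (150.0, 0.5),
            (200.0, 1.1),
            (260.0, 1.3),
            (300.0, 1.2),
        )
    )


def sit_flux(profiles=None) -> tuple[SITFluxProfile, SITFluxProfile, SITFluxProfile]:
    """Normalize a flux specification to a per-step triple of profiles.

    ``None`` means classical kinetics; a single profile applies to the two SIT
    steps (uptake and SDV import) with the deposition enzyme held constant,
    matching the biology that only transporter totals cycle.
    """
    if profiles is None:
        return constant_flux()
    if isinstance(profiles, SITFluxProfile):
        return (profiles, profiles, SITFluxProfile())
    profiles = tuple(profiles)
    if len(profiles) != 3:
        raise ValueError("flux must be None, one profile, or a triple")
    return profiles
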