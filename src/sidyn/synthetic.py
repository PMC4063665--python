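"""Synthetic population-level observation sets.

Emulates the statistical structure of a synchronized batch-culture experiment:
roughly ten medium silicic-acid samples over five hours, a cell-density curve
that is flat for ~2 h and then grows for ~3 h as the non-synchronized minority
divides, and a single end-point measurement of deposited silica per cell with
at least 5% relative error.  Observation noise is Gaussian with per-point
standard deviations that are recorded truthfully in the dataset, which makes
the weighted least-squares objective a proper likelihood-based fit criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Trajectory, simulate
from .params import (
    CultureConditions,
    KineticParameters,
    cell_density_curve,  # noqa: F401  (re-exported: the density curve is part of the data design)
    sit_flux,
)

QUANTITIES = ("medium_Si", "cell_density", "final_silica")


@dataclass(frozen=True)
class ObservationDesign:
    """Sampling plan for one synthetic experiment."""

    t_obs: tuple = tuple(np.linspace(0.0, 300.0, 10))
    rel_sd_S1: float = 0.05
    rel_sd_final: float = 0.05
    seed: int = 0
    include_density: bool = True
    #: multiplies the drawn noise only (recorded sds stay truthful); 0 gives a
    #: noise-free dataset with the same weights, for recovery experiments.
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_obs, dtype=float)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_obs must be non-empty and strictly increasing")
        if self.rel_sd_S1 <= 0:
            raise ValueError("rel_sd_S1 must be positive")
        if self.rel_sd_final < 0.05:
            raise ValueError("rel_sd_final must be at least 0.05")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass
class ObservedDataset:
    """Time-stamped observations with per-point standard deviations.

    ``records`` has columns ``quantity`` (one of medium_Si / cell_density /
    final_silica), ``time_min``, ``value``, ``sd``.  Exactly one final_silica
    record is allowed; all sds must be positive.  ``provenance`` carries the
    generating seed and true parameters when the dataset is synthetic.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"quantity", "time_min", "value", "sd"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        unknown = set(self.records["quantity"]) - set(QUANTITIES)
        if unknown:
            raise ValueError(f"unknown quantity tags: {sorted(unknown)}")
        if (self.records["sd"] <= 0).any():
            raise ValueError("all observation sds must be positive")
        n_final = int((self.records["quantity"] == "final_silica").sum())
        if n_final != 1:
            raise ValueError(f"expected exactly one final_silica record, got {n_final}")
        self.records = self.records.reset_index(drop=True)

    def subset(self, quantity: str) -> pd.DataFrame:
        return self.records[self.records["quantity"] == quantity]

    @property
    def n_fitted(self) -> int:
        """Number of records entering the objective (medium_Si + final_silica)."""
        return len(self.subset("medium_Si")) + 1

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservedDataset):
            return NotImplemented
        return self.records.equals(other.records)


def generate_dataset(
    true_params: KineticParameters,
    conditions: CultureConditions,
    flux=None,
    design: ObservationDesign | None = None,
    trajectory: Trajectory | None = None,
) -> ObservedDataset:
    """Simulate the forward model and observe it with Gaussian noise.

    Medium-silicon observations at ``design.t_obs`` get independent noise with
    sd ``rel_sd_S1 * model value``; the single deposited-silica end point (S4
    at the horizon) gets sd ``rel_sd_final * model value``.  Cell-density
    records carry the known growth curve (they are inputs to the model, not
    fitted, and are stored noise-free with a nominal sd).  Reproducible per
    seed; ``trajectory`` may pass a pre-computed forward solution on a grid
    containing the observation times.
    """
    design = design if design is not None else ObservationDesign()
    flux = sit_flux(flux)
    t_obs = np.asarray(design.t_obs, dtype=float)
    if t_obs[-1] > conditions.t_end:
        raise ValueError("observation times exceed the horizon")

    if trajectory is None:
        t_grid = np.unique(np.concatenate([[0.0], t_obs, [conditions.t_end]]))
        trajectory = simulate(true_params, conditions, flux, t_grid=t_grid)

    rng = np.random.default_rng(design.seed)
    rows = []

    s1_true = trajectory.interp("S1", t_obs)
    sd_s1 = design.rel_sd_S1 * np.abs(s1_true) + 1e-12
    s1_obs = s1_true + design.noise_scale * rng.normal(0.0, sd_s1)
    for t, v, sd in zip(t_obs, s1_obs, sd_s1):
        rows.append(("medium_Si", float(t), float(v), float(sd)))

    if design.include_density:
        N, _ = cell_density_curve(t_obs, conditions.N0, conditions.t_lag, conditions.growth_rate)
        for t, v in zip(t_obs, np.atleast_1d(N)):
            rows.append(("cell_density", float(t), float(v), float(0.01 * v)))

    s4_true = trajectory.interp("S4", conditions.t_end)
    sd_final = design.rel_sd_final * abs(s4_true) + 1e-12
    s4_obs = s4_true + design.noise_scale * rng.normal(0.0, sd_final)
    rows.append(("final_silica", float(conditions.t_end), float(s4_obs), float(sd_final)))

    records = pd.DataFrame(rows, columns=["quantity", "time_min", "value", "sd"])
    provenance = {
        "seed": int(design.seed),
        "true_theta": {k: float(v) for k, v in zip(
            ("K1", "K2", "K3", "kcat1", "kcat2", "kcat3", "E10", "E20", "E30"),
            true_params.theta(),
        )},
        "rel_sd_S1": design.rel_sd_S1,
        "rel_sd_final": design.rel_sd_final,
    }
    return ObservedDataset(records=records, provenance=provenance)
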