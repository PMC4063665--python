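"""End-to-end orchestration: data -> fit -> ensemble -> sensitivity -> perturbation.

A single recorded seed fans out deterministically to per-stage child seeds, so
any stage can be rerun in isolation and two runs with the same configuration
are identical (timestamps aside).
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    Objective,
    ObjectiveConfig,
    SearchOptions,
    SearchSpace,
    acceptance_set,
    scatter_search,
)
from .identifiability import (
    normalized_sensitivity,
    perturbation_analysis,
    scatter_dispersion,
    sensitivity_trajectories,
)
from .io import save_dataset, save_fit_result, save_table
from .model import simulate
from .params import (
    PARAM_NAMES,
    CultureConditions,
    KineticParameters,
    SITFluxProfile,
    sit_flux,
)
from .synthetic import ObservationDesign, generate_dataset


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full scenario + estimation configuration for one pipeline run."""

    params: KineticParameters = field(default_factory=KineticParameters)
    conditions: CultureConditions = field(default_factory=CultureConditions)
    flux: tuple | None = None
    design: ObservationDesign = field(default_factory=ObservationDesign)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    space: SearchSpace = field(default_factory=SearchSpace)
    options: SearchOptions | None = None
    seed: int = 0
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        flux = sit_flux(self.flux)
        return {
            "params": self.params.to_dict(),
            "conditions": self.conditions.to_dict(),
            "flux": [[list(map(float, k)) for k in p.knots] for p in flux],
            "design": {
                "t_obs": list(map(float, self.design.t_obs)),
                "rel_sd_S1": self.design.rel_sd_S1,
                "rel_sd_final": self.design.rel_sd_final,
                "seed": self.design.seed,
                "include_density": self.design.include_density,
                "noise_scale": self.design.noise_scale,
            },
            "objective": {
                "w": self.objective.w,
                "alpha": self.objective.alpha,
                "epsilon": self.objective.epsilon,
                "f_tol": self.objective.f_tol,
                "rtol": self.objective.rtol,
                "atol": self.objective.atol,
            },
            "space": {
                "names": list(self.space.names),
                "lower": list(map(float, self.space.lower)),
                "upper": list(map(float, self.space.upper)),
                "log_scale": list(map(bool, self.space.log_scale)),
            },
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "params" in d:
            cfg.params = KineticParameters(**d["params"])
        if "conditions" in d:
            cfg.conditions = CultureConditions(**d["conditions"])
        if "flux" in d and d["flux"] is not None:
            cfg.flux = tuple(
                SITFluxProfile(knots=tuple(tuple(k) for k in p)) for p in d["flux"]
            )
        if "design" in d:
            dd = dict(d["design"])
            dd["t_obs"] = tuple(dd.get("t_obs", ObservationDesign().t_obs))
            cfg.design = ObservationDesign(**dd)
        if "objective" in d:
            cfg.objective = ObjectiveConfig(**d["objective"])
        if "space" in d:
            s = d["space"]
            cfg.space = SearchSpace(
                names=tuple(s["names"]),
                lower=tuple(s["lower"]),
                upper=tuple(s["upper"]),
                log_scale=tuple(s["log_scale"]),
            )
        cfg.seed = int(d.get("seed", 0))
        cfg.out_dir = d.get("out_dir", "results/run")
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run_pipeline(config: RunConfig, dataset=None) -> dict:
    """Execute the five pipeline stages and write all artifacts.

    Stages: generate (or load) data -> fit -> acceptance ensemble ->
    sensitivity -> perturbation.  Returns a dict of the in-memory artifacts.
    Failures abort with the stage name; artifacts written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    artifacts: dict = {}
    flux = sit_flux(config.flux)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:
                log["stages"][name] = {"status": "failed", "error": str(err)}
                _write_log(log, out)
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
            log["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
            return result

        return wrap

    if dataset is None:
        def make_data():
            design = ObservationDesign(
                t_obs=config.design.t_obs,
                rel_sd_S1=config.design.rel_sd_S1,
                rel_sd_final=config.design.rel_sd_final,
                seed=child_seed(config.seed, "data"),
                include_density=config.design.include_density,
                noise_scale=config.design.noise_scale,
            )
            ds = generate_dataset(config.params, config.conditions, flux, design)
            save_dataset(ds, out / "dataset.csv")
            return ds

        dataset = stage("generate-data")(make_data)
    artifacts["dataset"] = dataset

    obj = Objective(dataset, config.conditions, flux, config.objective)
    options = config.options
    if options is None:
        options = SearchOptions(f_tol=obj.default_f_tol())

    def do_fit():
        result = scatter_search(obj, config.space, options, seed=child_seed(config.seed, "fit"))
        save_fit_result(result, out / "fit.yaml")
        return result

    fit = stage("fit")(do_fit)
    artifacts["fit"] = fit
    log["n_objective_evaluations"] = int(fit.n_evaluations)
    log["acceptance_tolerance"] = float(options.f_tol)
    log["stop_reason"] = fit.stop_reason

    def do_ensemble():
        thetas, objectives = acceptance_set((fit.thetas, fit.objectives), obj.default_f_tol())
        if len(thetas):
            disp = scatter_dispersion(thetas, config.space)
        else:
            disp = pd.DataFrame(columns=["parameter", "cv", "range_ratio", "scattered"])
        save_table(disp, out / "dispersion.csv")
        return thetas, objectives, disp

    artifacts["ensemble"] = stage("acceptance-set")(do_ensemble)

    best = fit.best_params

    def do_sens():
        raw = sensitivity_trajectories(best, config.conditions, flux)
        normed = normalized_sensitivity(raw, best)
        frame = normed.to_long_frame()
        save_table(frame, out / "sensitivity.csv")
        return normed

    artifacts["sensitivity"] = stage("sensitivity")(do_sens)

    def do_perturb():
        report = perturbation_analysis(
            best, dataset, config.conditions, flux, config=config.objective
        )
        save_table(report.table, out / "perturbation.csv")
        return report

    artifacts["perturbation"] = stage("perturbation")(do_perturb)

    _write_log(log, out)
    artifacts["log"] = log
    return artifacts


def _write_log(log: dict, out: Path) -> None:
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
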