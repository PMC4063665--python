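"""Dataset, configuration and result serialization (CSV + YAML, no binary formats)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .params import PARAM_NAMES
from .synthetic import ObservedDataset

DATASET_COLUMNS = ["quantity", "time_min", "value", "sd"]


def save_dataset(dataset: ObservedDataset, path) -> None:
    """Write the observation table as CSV plus a YAML provenance sidecar."""
    path = Path(path)
    dataset.records[DATASET_COLUMNS].to_csv(path, index=False)
    if dataset.provenance:
        sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(dataset.provenance, fh, sort_keys=True)


def load_dataset(path) -> ObservedDataset:
    """Read and validate an observation CSV (provenance sidecar if present)."""
    path = Path(path)
    records = pd.read_csv(path, float_precision="round_trip")
    missing = set(DATASET_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    provenance = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = yaml.safe_load(fh) or {}
    return ObservedDataset(records=records[DATASET_COLUMNS], provenance=provenance)


def save_fit_result(result: FitResult, path, ensemble_tol: float | None = None) -> None:
    """Serialize a fit as YAML (summary) plus a CSV ensemble table."""
    path = Path(path)
    summary = {
        "best_theta": {k: float(v) for k, v in zip(PARAM_NAMES, result.best_theta)},
        "best_objective": float(result.best_objective),
        "n_evaluations": int(result.n_evaluations),
        "seed": int(result.seed),
        "stop_reason": result.stop_reason,
        "f_tol": float(result.f_tol),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    thetas, objectives = result.ensemble(ensemble_tol)
    table = pd.DataFrame(thetas, columns=list(PARAM_NAMES))
    table["objective"] = objectives
    table.to_csv(path.with_suffix(".ensemble.csv"), index=False)


def load_fit_summary(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
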