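"""Plain-text readers/writers: trial tables and epochs as tidy CSV, traces
as CSV with a JSON sidecar, configs as YAML."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import TRIAL_COLUMNS, TaskConfig, validate_trials
from .photometry import PhotometryConfig, PhotometryTrace
from .preprocess import EpochMatrix

__all__ = [
    "write_trials", "read_trials",
    "write_trace", "read_trace",
    "write_epochs",
    "load_task_config", "load_photometry_config", "dump_config",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "session_id": str})
    if validate:
        validate_trials(df)
    return df


def write_trace(trace: PhotometryTrace, path: str | Path) -> None:
    """CSV of (sample_index, raw_f) plus a ``.json`` sidecar with site_id,
    sampling_rate and session boundaries."""
    path = Path(path)
    pd.DataFrame({"sample_index": np.arange(len(trace.samples)),
                  "raw_f": trace.samples}).to_csv(path, index=False)
    sidecar = {
        "site_id": trace.site_id,
        "sampling_rate": trace.sampling_rate,
        "session_offsets": [int(x) for x in trace.session_offsets],
        "session_ids": list(trace.session_ids),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_trace(path: str | Path) -> PhotometryTrace:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        side = json.load(fh)
    return PhotometryTrace(site_id=side["site_id"],
                           sampling_rate=side["sampling_rate"],
                           samples=df["raw_f"].to_numpy(),
                           session_offsets=side["session_offsets"],
                           session_ids=side["session_ids"])


def write_epochs(epochs: EpochMatrix, path: str | Path) -> None:
    """Long-format CSV: one row per (trial, timepoint)."""
    n, k = epochs.values.shape
    pd.DataFrame({
        "trial": np.repeat(epochs.trial_index_map, k),
        "time_s": np.tile(epochs.time_axis, n),
        "z": epochs.values.ravel(),
    }).to_csv(path, index=False)


def load_task_config(path: str | Path) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return TaskConfig(**raw.get("task", raw))


def load_photometry_config(path: str | Path) -> PhotometryConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PhotometryConfig(**raw.get("photometry", raw))


def dump_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh)
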