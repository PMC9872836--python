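"""Trial-log CSV schema (versioned header) and YAML run configuration."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .design import DesignSpec, get_design
from .observer import ObserverParams
from .session import TRIAL_LOG_COLUMNS

__all__ = [
    "TRIAL_LOG_VERSION",
    "write_trial_log",
    "read_trial_log",
    "RunConfig",
    "load_config",
]

TRIAL_LOG_VERSION = "cueddm-trial-log v1"

_DTYPES = {
    "subject_id": "int64",
    "block_index": "int64",
    "trial_index": "int64",
    "cue_object": "object",
    "space_valid": "bool",
    "feature_valid": "bool",
    "delay_ms": "int64",
    "gap_size_deg": "float64",
    "gap_side": "object",
    "response": "object",
    "rt_s": "float64",
    "gaze_contaminated": "bool",
    "is_guess": "bool",
}


def write_trial_log(log: pd.DataFrame, path) -> None:
    """Write a trial log as CSV with a versioned comment header."""
    path = Path(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# {TRIAL_LOG_VERSION}\n")
        log[TRIAL_LOG_COLUMNS].to_csv(fh, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read a trial-log CSV, validating the column schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: not a trial log; missing columns {missing}, "
            f"found {list(df.columns)}"
        )
    df = df[TRIAL_LOG_COLUMNS]
    return df.astype(_DTYPES)


@dataclasses.dataclass
class RunConfig:
    """Declarative run configuration (see ``examples/config_e1.yaml``).

    Either a simulation block (experiment + observer + n_subjects) or a
    trial-log path must be present.
    """

    experiment_id: str = "E1"
    n_subjects: int = 31
    observer: ObserverParams = dataclasses.field(default_factory=ObserverParams)
    log_path: str | None = None
    titrate: bool = True
    fast_cutoff_s: float | None = None
    min_correct: int = 2
    min_cell_n: int = 10
    n_seeds: int = 1

    @property
    def design(self) -> DesignSpec:
        return get_design(self.experiment_id)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "observer" in raw and raw["observer"] is not None:
        raw["observer"] = ObserverParams(**raw["observer"])
    cfg = RunConfig(**raw)
    if cfg.log_path is None and cfg.experiment_id is None:
        raise ValueError("config needs a simulation block or a log_path")
    return cfg
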