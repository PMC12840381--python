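"""Flat-file plumbing: ECG CSV / WFDB-style records, tables, configs.

Everything is plain text (CSV / JSON / YAML) so runs are inspectable and
reproducible at desk scale. A WFDB-style record is a two-file pair:
``<name>.hea`` with one header line (record name, channels, sampling rate,
length) and ``<name>.sig`` with one sample value (uV) per line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, StageError
from .synth import CohortConfig, ECGRecord, SubjectProfile


# --- ECG records -----------------------------------------------------------

def write_record_csv(record: ECGRecord, path: str | Path) -> None:
    """Two-column CSV: time_s, amplitude_uV."""
    t = np.arange(len(record.samples_uv)) / record.sampling_rate_hz
    df = pd.DataFrame({"time_s": np.round(t, 6),
                       "amplitude_uV": np.round(record.samples_uv, 3)})
    df.to_csv(path, index=False)


def read_record_csv(path: str | Path, subject_id: str | None = None
                    ) -> ECGRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise StageError(f"{path}: record too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(subject_id=subject_id or Path(path).stem,
                     sampling_rate_hz=round(fs, 3),
                     samples_uv=df["amplitude_uV"].to_numpy(dtype=float))


def write_record_wfdb(record: ECGRecord, basepath: str | Path) -> None:
    base = Path(basepath)
    header = (f"{base.stem} 1 {record.sampling_rate_hz:g} "
              f"{len(record.samples_uv)}\n"
              f"{base.stem}.sig 0 1(uV) I\n")
    base.with_suffix(".hea").write_text(header)
    np.savetxt(base.with_suffix(".sig"), record.samples_uv, fmt="%.3f")


def read_record_wfdb(basepath: str | Path) -> ECGRecord:
    base = Path(basepath)
    head = base.with_suffix(".hea").read_text().splitlines()[0].split()
    fs = float(head[2])
    samples = np.loadtxt(base.with_suffix(".sig"), dtype=float)
    return ECGRecord(subject_id=head[0], sampling_rate_hz=fs,
                     samples_uv=samples)


# --- cohort tables ---------------------------------------------------------

def write_cohort_csv(profiles: list[SubjectProfile], path: str | Path) -> None:
    rows = [dataclasses.asdict(p) for p in profiles]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("smoking", "diabetes", "hypertension"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df


# --- run configuration -----------------------------------------------------

STAGES = ["simulate", "delineate", "extract", "train", "evaluate"]

_RUNCONFIG_KEYS = {"stages", "seed", "out_dir", "log_level",
                   "simulate", "train", "evaluate"}


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; serialized into every output."""

    out_dir: str
    stages: list[str] = dataclasses.field(default_factory=lambda: list(STAGES))
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = dataclasses.field(default_factory=dict)
    train: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")

    def cohort_config(self) -> CohortConfig:
        known = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(self.simulate) - known
        if bad:
            raise ConfigurationError(f"unknown simulate keys: {sorted(bad)}")
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        return CohortConfig(**kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigurationError("config must set out_dir")
        return RunConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
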