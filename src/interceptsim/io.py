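"""File formats and run configuration.

Everything is delimited text. A trajectory file is a CSV with a commented
metadata header block::

    # participant: P01
    # kind: fast
    # trial_index: 17
    ...
    t_s,x_cm
    0.000,0.0132
    ...

Trial counts are small, so diffability beats compactness. A study
directory holds one trajectory file per exposure trial plus
``manifest.csv`` (one row of metadata/ground truth per trial) and
``participants.csv``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .geometry import TaskConfig
from .kinematics import KinematicsConfig, Trajectory
from .simulate import AgentDistributions, StudyData

__all__ = [
    "RunConfig",
    "write_trials",
    "read_trials",
    "trajectory_filename",
]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, round-trippable through YAML."""

    task: TaskConfig = field(default_factory=TaskConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    agents: AgentDistributions = field(default_factory=AgentDistributions)
    n_per_group: int = 20
    pos_noise_sd: float = 0.05
    alpha: float = 0.05
    seed: int = 7

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["agents"]["planned_mt_range"] = list(d["agents"]["planned_mt_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        out: Dict = {}
        if "task" in d:
            out["task"] = TaskConfig.from_dict(d.pop("task"))
        if "kinematics" in d:
            kd = d.pop("kinematics")
            bad = set(kd) - {f.name for f in fields(KinematicsConfig)}
            if bad:
                raise ConfigurationError(f"unknown kinematics keys: {sorted(bad)}")
            out["kinematics"] = KinematicsConfig(**kd)
        if "agents" in d:
            ad = dict(d.pop("agents"))
            bad = set(ad) - {f.name for f in fields(AgentDistributions)}
            if bad:
                raise ConfigurationError(f"unknown agents keys: {sorted(bad)}")
            if "planned_mt_range" in ad:
                ad["planned_mt_range"] = tuple(ad["planned_mt_range"])
            out["agents"] = AgentDistributions(**ad)
        out.update(d)
        return cls(**out)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# trajectory files
# ---------------------------------------------------------------------------

def trajectory_filename(participant: str, trial_index: int) -> str:
    return f"trial_{participant}_{trial_index:03d}.csv"


def _format_meta_value(v) -> str:
    if v is None:
        return "None"
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return repr(v) if isinstance(v, float) else str(v)


def _parse_meta_value(s: str):
    s = s.strip()
    if s == "None":
        return None
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    lines = [f"# {k}: {_format_meta_value(v)}" for k, v in sorted(traj.meta.items())]
    lines.append("t_s,x_cm")
    lines.extend(f"{t:.6f},{x:.9g}" for t, x in zip(traj.t, traj.x))
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    meta: Dict = {}
    header_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#"):
                header_rows += 1
                body = line[1:].strip()
                if ":" not in body:
                    raise DataError(f"{path.name}:{line_no}: malformed metadata line")
                k, v = body.split(":", 1)
                meta[k.strip()] = _parse_meta_value(v)
            else:
                break
    df = pd.read_csv(path, skiprows=header_rows)
    for col in ("t_s", "x_cm"):
        if col not in df.columns:
            raise DataError(f"{path.name}: missing column {col!r}")
    try:
        return Trajectory(df["t_s"].to_numpy(), df["x_cm"].to_numpy(), meta)
    except Exception as exc:
        raise DataError(f"{path.name}: {exc}") from exc


def write_trials(study: StudyData, out_dir) -> None:
    """Persist a simulated study: trajectory files + manifest + participants."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    part_rows = []
    for part in study.participants:
        part_rows.append({
            "participant": part.participant, "sex": part.sex,
            "group": part.group, "excluded": part.excluded,
            "learning_attempts": part.learning_attempts,
            **{f"agent_{k}": v for k, v in dataclasses.asdict(part.agent).items()},
        })
        for trial in part.trials:
            meta = trial.trajectory.meta
            write_trajectory(
                trial.trajectory,
                out / trajectory_filename(part.participant, meta["trial_index"]),
            )
            manifest_rows.append(dict(meta))
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(part_rows).to_csv(out / "participants.csv", index=False)


def read_trials(in_dir) -> List[Trajectory]:
    """Read every trajectory file in a study directory (sorted order)."""
    in_dir = Path(in_dir)
    if not in_dir.is_dir():
        raise DataError(f"{in_dir} is not a directory")
    files = sorted(in_dir.glob("trial_*.csv"))
    if not files:
        raise DataError(f"no trajectory files in {in_dir}")
    return [read_trajectory(f) for f in files]


def read_participants(in_dir) -> pd.DataFrame:
    path = Path(in_dir) / "participants.csv"
    if not path.exists():
        raise DataError(f"{path} not found")
    return pd.read_csv(path)
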