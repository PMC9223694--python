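"""Reading and writing the pipeline's tabular formats and configs.

Trajectory tables are long-form CSV with the header
``cell_id,time_h,F,total_fluorescence,temperature_C,coating``; times are
hours relative to stress onset and F is a fraction in [0, 1].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from hsr.model import CellTrajectory, ModelParameters, TemperatureProtocol
from hsr.population import PopulationSpec

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "load_config",
    "dump_config",
]

TRAJECTORY_COLUMNS = ["cell_id", "time_h", "F", "total_fluorescence", "temperature_C", "coating"]


def trajectories_to_frame(trajectories: Iterable[CellTrajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for t, f, fl in zip(traj.times, traj.f_values, traj.total_fluorescence):
            rows.append((traj.cell_id, float(t), float(f), float(fl),
                         traj.temperature_c, traj.coating))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def frame_to_trajectories(frame: pd.DataFrame) -> list[CellTrajectory]:
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    out = []
    for cell_id, group in frame.groupby("cell_id", sort=False):
        group = group.sort_values("time_h")
        out.append(
            CellTrajectory(
                cell_id=str(cell_id),
                times=group["time_h"].to_numpy(),
                f_values=group["F"].to_numpy(),
                total_fluorescence=group["total_fluorescence"].to_numpy(),
                temperature_c=float(group["temperature_C"].iloc[0]),
                coating=str(group["coating"].iloc[0]),
            )
        )
    return out


def write_trajectories(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[CellTrajectory]:
    return frame_to_trajectories(pd.read_csv(path))


def load_config(path: str | Path) -> dict:
    """Load a YAML config into (params, protocol, population) objects.

    Recognised top-level keys: ``model`` (ModelParameters fields),
    ``protocol`` (either ``segments: [[start, end, setpoint], ...]`` or a
    ``stress_temperature``/``stress_duration``/``pre``/``post`` step
    shorthand) and ``population`` (PopulationSpec fields).  Missing keys
    fall back to the built-in reference defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = ModelParameters(**raw.get("model", {}))
    proto_cfg = raw.get("protocol", {})
    if "segments" in proto_cfg:
        protocol = TemperatureProtocol(
            segments=tuple(tuple(seg) for seg in proto_cfg["segments"]),
            theta0=proto_cfg.get("theta0", 37.0),
        )
    elif proto_cfg:
        protocol = TemperatureProtocol.step(
            proto_cfg["stress_temperature"],
            proto_cfg.get("stress_duration", 3.0),
            pre=proto_cfg.get("pre", 1.0),
            post=proto_cfg.get("post", 1.0),
        )
    else:
        protocol = None
    population = PopulationSpec(**raw.get("population", {})) if "population" in raw else None
    return {"model": params, "protocol": protocol, "population": population, "raw": raw}


def dump_config(path: str | Path, params: ModelParameters | None = None,
                population: PopulationSpec | None = None) -> None:
    """Echo fully-resolved settings back to YAML (provenance sidecar)."""
    doc: dict = {}
    if params is not None:
        doc["model"] = dataclasses.asdict(params)
    if population is not None:
        doc["population"] = dataclasses.asdict(population)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
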