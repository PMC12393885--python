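"""Serialization of genomes, trajectories and run provenance."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import Genome, STATE_NEURONS
from .errors import KlinosimError
from .simulator import Trajectory

TRAJECTORY_COLUMNS = ("t", "x", "y", "heading", "phi", "conc")


class TrajectoryParseError(KlinosimError, ValueError):
    """A trajectory file is malformed; carries the offending line number."""


def write_genome(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        json.dump(list(genome.values), fh)


def read_genome(path) -> Genome:
    with open(path) as fh:
        return Genome.from_array(json.load(fh))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as tidy CSV (one row per step, documented column
    order; state traces appended when recorded)."""
    traj.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        line = getattr(exc, "lineno", None)
        raise TrajectoryParseError(f"cannot parse {path}: {exc}"
                                   + (f" (line {line})" if line else "")) from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        dt = 0.01
    else:
        dt = float(df["t"].iloc[1] - df["t"].iloc[0]) if len(df) > 1 else 0.01
    traj = Trajectory(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        heading=df["heading"].to_numpy(), phi=df["phi"].to_numpy(),
        conc=df["conc"].to_numpy(), dt=dt,
    )
    if f"z_{STATE_NEURONS[0]}" in df.columns:
        traj.y_state = np.column_stack(
            [df[f"y_{n}"].to_numpy() for n in STATE_NEURONS])
        traj.z_state = np.column_stack(
            [df[f"z_{n}"].to_numpy() for n in STATE_NEURONS])
        traj.z_on = df["z_on"].to_numpy()
        traj.z_off = df["z_off"].to_numpy()
    return traj


def write_provenance(path, config: dict, seed, extra: dict | None = None) -> None:
    """Record enough metadata (config, seed, version) to reproduce a run."""
    from . import __version__

    record = {"package": "klinosim", "version": __version__,
              "seed": seed, "config": config}
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=1, default=str))
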