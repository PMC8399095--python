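"""CSV/JSON readers and writers plus run manifests.

Trajectories travel as CSV with header ``t,x,y[,vx,vy,ax,ay]`` (``time``
is accepted as an alias for ``t``); landmark streams as CSV with ``t``
plus ``x_<name>,y_<name>`` column pairs.  Units are seconds and metres
(or pixels for uncalibrated camera streams).  A run manifest (JSON)
records the seed, a config hash and per-stage parameters so that runs are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import LANDMARKS, LandmarkSeries, TrajectorySeries


class ParseError(ValueError):
    pass


_TRAJ_COLS = ("t", "x", "y", "vx", "vy", "ax", "ay")


def read_trajectory(path, provenance: str = "com") -> TrajectorySeries:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "time" in df.columns and "t" not in df.columns:
        df = df.rename(columns={"time": "t"})
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}")
    try:
        arrs = {c: df[c].astype(float).to_numpy()
                for c in _TRAJ_COLS if c in df.columns}
    except ValueError as exc:
        raise ParseError(f"non-numeric cell in trajectory file: {exc}") from exc
    if np.any(np.diff(arrs["t"]) <= 0):
        raise ParseError("time column must be strictly increasing")
    return TrajectorySeries(provenance=provenance, **arrs)


def write_trajectory(series: TrajectorySeries, path) -> None:
    cols = {"t": series.t, "x": series.x, "y": series.y}
    for name in ("vx", "vy", "ax", "ay"):
        v = getattr(series, name)
        if v is not None:
            cols[name] = v
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_landmarks(path, known=LANDMARKS) -> LandmarkSeries:
    """Read a landmark CSV; unknown landmark columns are ignored with a
    warning, frames with missing entries stay NaN-flagged."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "time" in df.columns and "t" not in df.columns:
        df = df.rename(columns={"time": "t"})
    if "t" not in df.columns:
        raise ParseError("missing time column")
    names = set()
    for c in df.columns:
        if c.startswith(("x_", "y_")):
            names.add(c[2:])
    unknown = sorted(names - set(known))
    if unknown:
        import warnings
        warnings.warn(f"ignoring unknown landmarks: {', '.join(unknown)}")
    names = sorted(names & set(known))
    if not names:
        raise ParseError("no known landmark columns found")
    t = df["t"].astype(float).to_numpy()
    pts = {}
    for n in names:
        x = df.get(f"x_{n}")
        y = df.get(f"y_{n}")
        if x is None or y is None:
            continue
        pts[n] = np.column_stack([x.astype(float), y.astype(float)])
    return LandmarkSeries(t, pts)


def write_landmarks(frames: LandmarkSeries, path) -> None:
    cols = {"t": frames.t}
    for name in sorted(frames.points):
        cols[f"x_{name}"] = frames.points[name][:, 0]
        cols[f"y_{name}"] = frames.points[name][:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    seed: int
    config: dict
    inputs: list = field(default_factory=list)
    tool_version: str = "0.1.0"

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "config_hash": self.config_hash,
                       "tool_version": self.tool_version,
                       "inputs": self.inputs, "config": self.config},
                      fh, indent=2, default=str)
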