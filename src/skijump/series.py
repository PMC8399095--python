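"""Uniformly sampled trajectory and landmark containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrajectorySeries:
    """Uniformly sampled 2D point kinematics.

    Velocity/acceleration channels are optional (None until derived).
    ``provenance`` records which physical point the series tracks:
    ``"com"``, ``"head"`` or ``"antenna"``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    ax: np.ndarray | None = None
    ay: np.ndarray | None = None
    provenance: str = "com"
    rate_hz: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) != len(self.x) or len(self.t) != len(self.y):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if self.rate_hz is None and np.allclose(dt, dt[0], rtol=1e-6):
                self.rate_hz = 1.0 / dt[0]
        for name in ("vx", "vy", "ax", "ay"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def speed(self) -> np.ndarray:
        if self.vx is None or self.vy is None:
            raise ValueError("velocity channels not present")
        return np.hypot(self.vx, self.vy)

    def window(self, t0: float = -np.inf, t1: float = np.inf) -> "TrajectorySeries":
        """Sub-series with t0 <= t <= t1."""
        m = (self.t >= t0) & (self.t <= t1)
        if not m.any():
            raise ValueError("requested window outside the series")
        kw = {n: (getattr(self, n)[m] if getattr(self, n) is not None else None)
              for n in ("vx", "vy", "ax", "ay")}
        return TrajectorySeries(self.t[m], self.x[m], self.y[m],
                                provenance=self.provenance,
                                rate_hz=self.rate_hz, **kw)

    def window_x(self, x0: float, x1: float) -> "TrajectorySeries":
        """Sub-series with x0 <= x <= x1 (x monotone assumed)."""
        m = (self.x >= x0) & (self.x <= x1)
        if not m.any():
            raise ValueError("requested x window outside the series")
        kw = {n: (getattr(self, n)[m] if getattr(self, n) is not None else None)
              for n in ("vx", "vy", "ax", "ay")}
        return TrajectorySeries(self.t[m], self.x[m], self.y[m],
                                provenance=self.provenance,
                                rate_hz=self.rate_hz, **kw)


#: canonical right-side sagittal landmark names
LANDMARKS = ("head_top", "upper_neck", "shoulder", "elbow", "wrist",
             "upper_chest", "hip", "knee", "ankle")


@dataclass
class LandmarkSeries:
    """Time series of named 2D landmarks (one sagittal pose per frame).

    ``points`` maps landmark name -> (n, 2) array.  Missing landmarks in a
    frame are NaN; ``present`` tells whether a landmark is finite in a
    given frame.  Units are pixels for raw camera data, metres once
    calibrated (``calibrated`` flag).
    """

    t: np.ndarray
    points: dict[str, np.ndarray]
    calibrated: bool = True
    rate_hz: float | None = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for k, v in self.points.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.t), 2):
                raise ValueError(f"landmark {k!r} must be (n, 2)")
            self.points[k] = v
        if self.rate_hz is None and len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.allclose(dt, dt[0], rtol=1e-6):
                self.rate_hz = 1.0 / dt[0]

    def __len__(self) -> int:
        return len(self.t)

    def present(self, name: str) -> np.ndarray:
        """Boolean mask of frames where the landmark is finite."""
        if name not in self.points:
            return np.zeros(len(self.t), dtype=bool)
        return np.isfinite(self.points[name]).all(axis=1)

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {k: v[i] for k, v in self.points.items()
                if np.isfinite(v[i]).all()}
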