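"""Parametric jumping-hill geometry.

The in-run is modelled as three C1-joined segments traversed by increasing
arc length ``s``: an upper straight at a constant slope, a circular
transition of radius ``r`` that rotates the track from the straight slope to
the take-off table slope, and the straight table itself.  The local frame
has its origin at the in-run edge (end of the table), ``x`` positive in the
flight direction and ``y`` positive up; all angles are stored in radians as
positive magnitudes below the horizontal.

The landing hill is a monotone-in-x piecewise-cubic Hermite profile
``y(x) <= 0`` for ``x >= 0``; jump distances are measured as arc length
along this profile, which is how competition distances are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import quad
from scipy.interpolate import CubicHermiteSpline
from scipy.optimize import brentq


class HillDomainError(ValueError):
    """Raised when a query falls outside the modelled hill."""


class NoLandingError(RuntimeError):
    """Raised when a trajectory never intersects the landing profile."""


@dataclass(frozen=True)
class HillProfile:
    """Geometry of one jumping hill (in-run plus landing hill).

    Parameters
    ----------
    inrun_straight_angle:
        Slope of the upper in-run straight, radians below horizontal (> 0).
    transition_radius:
        Radius of the circular in-run transition, m.
    table_angle:
        Slope of the take-off table, radians below horizontal.
    table_length:
        Length of the take-off table, m.
    inrun_total_arc_length:
        Arc length from the top of the modelled in-run (s = 0) to the edge.
    landing_knots:
        Sequence of ``(x, y, dy/dx)`` knots, strictly increasing in x,
        interpolated with a C1 cubic Hermite spline.
    k_point_distance:
        K-point position measured along the landing profile, m.
    gate_ref, gate_ref_arc_position, gate_spacing:
        Start-gate bookkeeping: gate ``gate_ref`` sits at arc position
        ``gate_ref_arc_position``; each lower gate moves the start
        ``gate_spacing`` metres further down the in-run.
    """

    inrun_straight_angle: float
    transition_radius: float
    table_angle: float
    table_length: float
    inrun_total_arc_length: float
    landing_knots: tuple[tuple[float, float, float], ...]
    k_point_distance: float = 95.0
    gate_ref: int = 15
    gate_ref_arc_position: float = 0.0
    gate_spacing: float = 0.8
    _spline: CubicHermiteSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.transition_radius <= 0:
            raise ValueError("transition_radius must be > 0")
        if not 0 < self.table_angle < self.inrun_straight_angle:
            raise ValueError("require 0 < table_angle < inrun_straight_angle")
        if self.arc_length < 0 or self.straight_length < 0:
            raise ValueError("inrun_total_arc_length too short for the "
                             "configured transition and table")
        knots = np.asarray(self.landing_knots, dtype=float)
        if knots.ndim != 2 or knots.shape[1] != 3 or len(knots) < 2:
            raise ValueError("landing_knots must be (x, y, dydx) triples")
        if np.any(np.diff(knots[:, 0]) <= 0):
            raise ValueError("landing knot x values must strictly increase")
        spline = CubicHermiteSpline(knots[:, 0], knots[:, 1], knots[:, 2])
        object.__setattr__(self, "_spline", spline)

    # -- in-run segment bookkeeping -------------------------------------

    @property
    def arc_length(self) -> float:
        """Arc length of the circular transition."""
        return self.transition_radius * (self.inrun_straight_angle - self.table_angle)

    @property
    def straight_length(self) -> float:
        return self.inrun_total_arc_length - self.arc_length - self.table_length

    @property
    def s_curve_start(self) -> float:
        return self.straight_length

    @property
    def s_table_start(self) -> float:
        return self.straight_length + self.arc_length

    def gate_arc_position(self, gate: int) -> float:
        """Arc position s of a numbered start gate (higher gate = higher up)."""
        s = self.gate_ref_arc_position + (self.gate_ref - gate) * self.gate_spacing
        if not 0 <= s < self.inrun_total_arc_length:
            raise HillDomainError(f"gate {gate} lies outside the modelled in-run")
        return s

    # -- in-run state ----------------------------------------------------

    def inrun_slope(self, s: float) -> float:
        """Track slope below horizontal (rad) at arc position s."""
        self._check_s(s)
        if s <= self.s_curve_start:
            return self.inrun_straight_angle
        if s <= self.s_table_start:
            return self.inrun_straight_angle - (s - self.s_curve_start) / self.transition_radius
        return self.table_angle

    def inrun_curvature(self, s: float) -> float:
        """Curvature (1/m): 0 on the straights, 1/r on the transition."""
        self._check_s(s)
        if self.s_curve_start < s < self.s_table_start:
            return 1.0 / self.transition_radius
        return 0.0

    def inrun_position(self, s: float) -> np.ndarray:
        """Track position (x, y) in the edge frame at arc position s."""
        self._check_s(s)
        # integrate the unit tangent (cos d, -sin d) backwards from the edge
        x = 0.0
        y = 0.0
        dt = self.table_angle
        # table portion behind the edge
        table_run = min(self.inrun_total_arc_length - s, self.table_length)
        x -= table_run * np.cos(dt)
        y += table_run * np.sin(dt)
        if s >= self.s_table_start:
            return np.array([x, y])
        # circular portion: closed-form integral of the rotating tangent
        d_at_s = self.inrun_slope(max(s, self.s_curve_start))
        r = self.transition_radius
        x -= r * (np.sin(d_at_s) - np.sin(dt))
        y += r * (np.cos(dt) - np.cos(d_at_s))
        if s >= self.s_curve_start:
            return np.array([x, y])
        d0 = self.inrun_straight_angle
        run = self.s_curve_start - s
        x -= run * np.cos(d0)
        y += run * np.sin(d0)
        return np.array([x, y])

    def inrun_state_at(self, s: float) -> tuple[np.ndarray, float, float]:
        """Position, slope angle (rad below horizontal) and curvature at s."""
        return self.inrun_position(s), self.inrun_slope(s), self.inrun_curvature(s)

    def _check_s(self, s: float) -> None:
        if not 0 <= s <= self.inrun_total_arc_length:
            raise HillDomainError(
                f"arc position {s} outside [0, {self.inrun_total_arc_length}]")

    # -- landing hill ----------------------------------------------------

    @property
    def landing_x_max(self) -> float:
        return float(self.landing_knots[-1][0])

    def landing_height(self, x: float | np.ndarray) -> float | np.ndarray:
        """Hill height y(x) of the landing profile, m (single-valued)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.landing_knots[0][0]) or np.any(x > self.landing_x_max):
            raise HillDomainError("x outside the landing-profile domain")
        out = self._spline(x)
        return float(out) if out.ndim == 0 else out

    def landing_slope(self, x: float) -> float:
        """dy/dx of the landing profile."""
        if not self.landing_knots[0][0] <= x <= self.landing_x_max:
            raise HillDomainError("x outside the landing-profile domain")
        return float(self._spline.derivative()(x))

    def distance_along_profile(self, x_landing: float) -> float:
        """Competition jump distance: arc length of y(x) from x = 0 to x_landing."""
        if not 0 <= x_landing <= self.landing_x_max:
            raise HillDomainError("x outside the landing-profile domain")
        deriv = self._spline.derivative()
        knots = [k[0] for k in self.landing_knots if 0.0 < k[0] < x_landing]
        val, _ = quad(lambda u: float(np.hypot(1.0, deriv(u))), 0.0, x_landing,
                      points=knots or None, limit=200)
        return val

    def find_landing(self, trajectory, offset: float = 0.0) -> tuple[float, float]:
        """First crossing of a trajectory (height minus ``offset``) with the hill.

        ``trajectory`` is any object with ``t``, ``x``, ``y`` array attributes.
        Returns ``(landing_x, landing_time)`` with linear interpolation
        between bracketing samples.
        """
        t = np.asarray(trajectory.t, float)
        x = np.asarray(trajectory.x, float)
        y = np.asarray(trajectory.y, float)
        inside = (x >= self.landing_knots[0][0]) & (x <= self.landing_x_max)
        if not inside.any():
            raise NoLandingError("trajectory never enters the landing domain")
        idx = np.flatnonzero(inside)
        clearance = y[idx] - offset - self._spline(x[idx])
        below = np.flatnonzero(clearance <= 0)
        if below.size == 0:
            raise NoLandingError("trajectory stays above the landing profile")
        j = below[0]
        if j == 0:
            return float(x[idx[0]]), float(t[idx[0]])
        i0, i1 = idx[j - 1], idx[j]
        c0, c1 = clearance[j - 1], clearance[j]
        w = c0 / (c0 - c1)
        return (float(x[i0] + w * (x[i1] - x[i0])),
                float(t[i0] + w * (t[i1] - t[i0])))


def hill_from_dict(cfg: dict) -> HillProfile:
    """Build a :class:`HillProfile` from a config mapping (angles in degrees)."""
    knots = tuple((float(k[0]), float(k[1]), float(k[2]))
                  for k in cfg["landing_knots"])
    return HillProfile(
        inrun_straight_angle=np.deg2rad(cfg["inrun_straight_angle_deg"]),
        transition_radius=float(cfg["transition_radius_m"]),
        table_angle=np.deg2rad(cfg["table_angle_deg"]),
        table_length=float(cfg["table_length_m"]),
        inrun_total_arc_length=float(cfg["inrun_total_arc_length_m"]),
        landing_knots=knots,
        k_point_distance=float(cfg.get("k_point_distance_m", 95.0)),
        gate_ref=int(cfg.get("gate_ref", 15)),
        gate_ref_arc_position=float(cfg.get("gate_ref_arc_position_m", 0.0)),
        gate_spacing=float(cfg.get("gate_spacing_m", 0.8)),
    )


def load_hill(path) -> HillProfile:
    """Read hill geometry from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return hill_from_dict(cfg.get("hill", cfg))
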