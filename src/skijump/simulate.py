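"""Physics-based synthetic jump generator and ground-truth oracle.

A point-mass model is integrated with classical fixed-step RK4 (default
1 ms) through the three phases of a jump:

* **in-run** — along-track dynamics on the hill profile, driven by gravity
  and braked by ski friction ``mu * FN`` (with the centripetal
  contribution to the normal force in the curved transition) and
  aerodynamic drag ``0.5 rho v^2 CDA``;
* **take-off** — an instantaneous perpendicular velocity impulse at the
  edge (the jumper's push-off), leaving the along-track speed unchanged;
* **flight** — ballistic motion with drag antiparallel and lift
  perpendicular to the velocity, terminated at the landing-profile
  intersection.

Every step's applied forces are recorded so inverse-dynamics estimates can
be validated pointwise against the generating truth.  On top of the CoM
trajectory, a sagittal landmark stream is synthesised from parametrised
knee/hip/angle-of-attack profiles, and noisy "sensors" (50 Hz dGNSS-like
antenna, 60 Hz camera landmarks) are sampled from the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .body import SegmentModel, compute_com
from .hill import HillProfile
from .series import LandmarkSeries, TrajectorySeries


class SimulationError(RuntimeError):
    pass


def _as_fn(value) -> Callable[[float], float]:
    if callable(value):
        return value
    return lambda _t, _v=float(value): _v


@dataclass
class SimulationConfig:
    """Physical parameters of one synthetic jump.

    Aerodynamic areas are the identifiable products C_D*A / C_L*A (m^2);
    each may be a constant or a callable (of arc position for the in-run,
    of time since take-off for flight).  Defaults describe a realistic
    crouched in-run and a stable flight posture.
    """

    m: float = 65.0                      # body mass, kg
    equipment_mass: float = 10.0         # helmet + boots + skis, kg
    g: float = 9.81
    mu: float = 0.03                     # ski-snow friction coefficient
    rho: float = 1.225                   # air density, kg/m^3
    cda_inrun: float | Callable = 0.22
    cda_flight: float | Callable = 0.44
    cla_flight: float | Callable = 0.58
    takeoff_impulse_vperp: float = 2.3   # m/s, perpendicular push-off
    gate: int = 15
    step: float = 1e-3                   # RK4 step, s
    seed: int = 0

    def __post_init__(self):
        if self.m <= 0 or self.rho <= 0 or self.step <= 0:
            raise ValueError("m, rho and step must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def total_mass(self) -> float:
        return self.m + self.equipment_mass


@dataclass
class ForceRecord:
    """Forces applied by the simulator at each sample (the oracle)."""

    FD: np.ndarray
    FL: np.ndarray
    FN: np.ndarray
    Ff: np.ndarray


@dataclass
class PhaseResult:
    series: TrajectorySeries
    forces: ForceRecord
    # arc position (in-run) is kept for curvature-aware checks
    s: np.ndarray | None = None


def simulate_inrun(cfg: SimulationConfig, hill: HillProfile,
                   record_every: int = 1) -> PhaseResult:
    """Integrate the in-run from a standing start at the gate to the edge.

    State is (s, v) along the track; dv/dt = g sin(delta) - (mu*FN +
    0.5 rho v^2 CDA)/m with FN = m (g cos(delta) + v^2 kappa).  The final
    sample lands exactly on the in-run edge by interpolating the last step.
    """
    s0 = hill.gate_arc_position(cfg.gate)
    L = hill.inrun_total_arc_length
    m = cfg.total_mass
    cda = _as_fn(cfg.cda_inrun)

    def accel(s, v):
        s = min(max(s, 0.0), L)  # RK substeps may probe just outside
        delta = hill.inrun_slope(s)
        kappa = hill.inrun_curvature(s)
        fn = m * (cfg.g * np.cos(delta) + v * v * kappa)
        fd = 0.5 * cfg.rho * v * v * cda(s)
        return cfg.g * np.sin(delta) - (cfg.mu * fn + fd) / m

    dt = cfg.step
    ts, ss, vs = [0.0], [s0], [0.0]
    t, s, v = 0.0, s0, 0.0
    max_steps = int(60.0 / dt)
    for _ in range(max_steps):
        k1s, k1v = v, accel(s, v)
        k2s, k2v = v + 0.5 * dt * k1v, accel(s + 0.5 * dt * k1s, v + 0.5 * dt * k1v)
        k3s, k3v = v + 0.5 * dt * k2v, accel(s + 0.5 * dt * k2s, v + 0.5 * dt * k2v)
        k4s, k4v = v + dt * k3v, accel(s + dt * k3s, v + dt * k3v)
        s_new = s + dt / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
        v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += dt
        if v_new < 0:
            raise SimulationError("athlete stalled on the in-run")
        if s_new >= L:
            # interpolate the crossing so the last sample is the edge
            w = (L - s) / (s_new - s)
            ts.append(t - dt + w * dt)
            ss.append(L)
            vs.append(v + w * (v_new - v))
            break
        s, v = s_new, v_new
        ts.append(t)
        ss.append(s)
        vs.append(v)
    else:
        raise SimulationError("in-run did not reach the edge")

    ts = np.asarray(ts)
    ss = np.asarray(ss)
    vs = np.asarray(vs)
    if record_every > 1:
        keep = np.arange(0, len(ts), record_every)
        if keep[-1] != len(ts) - 1:  # keep the exact edge sample
            keep = np.append(keep, len(ts) - 1)
        ts, ss, vs = ts[keep], ss[keep], vs[keep]

    delta = np.array([hill.inrun_slope(si) for si in ss])
    kappa = np.array([hill.inrun_curvature(si) for si in ss])
    pos = np.array([hill.inrun_position(si) for si in ss])
    tang = np.column_stack([np.cos(delta), -np.sin(delta)])
    nrm = np.column_stack([np.sin(delta), np.cos(delta)])  # up-normal
    FN = m * (cfg.g * np.cos(delta) + vs ** 2 * kappa)
    FD = 0.5 * cfg.rho * vs ** 2 * np.array([cda(si) for si in ss])
    Ff = cfg.mu * FN
    vdot = cfg.g * np.sin(delta) - (Ff + FD) / m
    acc = vdot[:, None] * tang + (vs ** 2 * kappa)[:, None] * nrm
    vel = vs[:, None] * tang
    series = TrajectorySeries(ts, pos[:, 0], pos[:, 1],
                              vx=vel[:, 0], vy=vel[:, 1],
                              ax=acc[:, 0], ay=acc[:, 1], provenance="com")
    return PhaseResult(series, ForceRecord(FD, np.zeros_like(FD), FN, Ff), s=ss)


def apply_takeoff(state: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Add the take-off impulse perpendicular to the velocity (toward up).

    ``state`` is (x, y, vx, vy); the along-track speed is unchanged and
    the new speed is sqrt(v^2 + w^2).
    """
    x, y, vx, vy = state
    sp = np.hypot(vx, vy)
    if sp == 0:
        raise SimulationError("cannot take off with zero speed")
    n = np.array([-vy, vx]) / sp  # velocity rotated +90 deg: up-normal
    w = cfg.takeoff_impulse_vperp
    return np.array([x, y, vx + w * n[0], vy + w * n[1]])


def simulate_flight(cfg: SimulationConfig, hill: HillProfile,
                    state0: np.ndarray, landing_offset: float = 0.0,
                    record_every: int = 1) -> tuple[PhaseResult, float, float]:
    """Integrate airborne motion until the trajectory meets the landing hill.

    Acceleration is -g y_hat + (-FD v_hat + FL n_hat)/m with n_hat the
    velocity direction rotated +90 deg (toward up for descending motion).
    Returns ``(phase, landing_x, landing_t)``; the series ends at the last
    sample above the hill.
    """
    m = cfg.total_mass
    cda = _as_fn(cfg.cda_flight)
    cla = _as_fn(cfg.cla_flight)

    def deriv(t, y):
        x, yy, vx, vy = y
        sp = np.hypot(vx, vy)
        if not np.isfinite(sp):
            raise SimulationError("non-finite state in flight integration")
        fd = 0.5 * cfg.rho * sp * sp * cda(t)
        fl = 0.5 * cfg.rho * sp * sp * cla(t)
        if sp > 0:
            ux, uy = vx / sp, vy / sp
        else:
            ux, uy = 1.0, 0.0
        axv = (-fd * ux - fl * uy) / m
        ayv = (-fd * uy + fl * ux) / m - cfg.g
        return np.array([vx, vy, axv, ayv])

    dt = cfg.step
    y = np.asarray(state0, dtype=float)
    t = 0.0
    rows = [np.concatenate([[t], y, deriv(t, y)[2:]])]
    max_steps = int(20.0 / dt)
    for _ in range(max_steps):
        k1 = deriv(t, y)
        k2 = deriv(t + dt / 2, y + dt / 2 * k1)
        k3 = deriv(t + dt / 2, y + dt / 2 * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        rows.append(np.concatenate([[t], y, deriv(t, y)[2:]]))
        if (y[0] > hill.landing_knots[0][0]
                and y[0] <= hill.landing_x_max
                and y[1] - landing_offset <= hill.landing_height(y[0])):
            break
        if y[0] > hill.landing_x_max:
            break
    arr = np.array(rows)
    if record_every > 1:
        dec = arr[::record_every]
        if dec[-1, 0] != arr[-1, 0]:  # keep the crossing sample
            dec = np.vstack([dec, arr[-1]])
        arr = dec
    series = TrajectorySeries(arr[:, 0], arr[:, 1], arr[:, 2],
                              vx=arr[:, 3], vy=arr[:, 4],
                              ax=arr[:, 5], ay=arr[:, 6], provenance="com")
    x_land, t_land = hill.find_landing(series, offset=landing_offset)
    keep = series.t <= t_land
    sp = np.hypot(arr[:, 3], arr[:, 4])
    FD = 0.5 * cfg.rho * sp ** 2 * np.array([cda(ti) for ti in arr[:, 0]])
    FL = 0.5 * cfg.rho * sp ** 2 * np.array([cla(ti) for ti in arr[:, 0]])
    series = TrajectorySeries(arr[keep, 0], arr[keep, 1], arr[keep, 2],
                              vx=arr[keep, 3], vy=arr[keep, 4],
                              ax=arr[keep, 5], ay=arr[keep, 6],
                              provenance="com")
    forces = ForceRecord(FD[keep], FL[keep],
                         np.zeros(keep.sum()), np.zeros(keep.sum()))
    return PhaseResult(series, forces), x_land, t_land


@dataclass
class JumpResult:
    """Complete synthetic jump: phase truths stitched into one timeline.

    ``t = 0`` at the in-run edge (take-off); the in-run carries negative
    times.  ``com`` concatenates both phases on a uniform clock.
    """

    inrun: PhaseResult
    flight: PhaseResult
    com: TrajectorySeries
    edge_speed: float
    landing_x: float
    landing_t: float
    distance: float


def simulate_jump(cfg: SimulationConfig, hill: HillProfile,
                  record_every: int = 10) -> JumpResult:
    """In-run + take-off impulse + flight, with competition jump distance."""
    inrun = simulate_inrun(cfg, hill, record_every=record_every)
    st = inrun.series
    edge_state = np.array([st.x[-1], st.y[-1], st.vx[-1], st.vy[-1]])
    edge_speed = float(np.hypot(edge_state[2], edge_state[3]))
    state0 = apply_takeoff(edge_state, cfg)
    flight, x_land, t_land = simulate_flight(cfg, hill, state0,
                                             record_every=record_every)
    # shift in-run times so take-off is t = 0
    t_in = st.t - st.t[-1]
    fs = flight.series
    com = TrajectorySeries(
        np.concatenate([t_in[:-1], fs.t]),
        np.concatenate([st.x[:-1], fs.x]),
        np.concatenate([st.y[:-1], fs.y]),
        vx=np.concatenate([st.vx[:-1], fs.vx]),
        vy=np.concatenate([st.vy[:-1], fs.vy]),
        ax=np.concatenate([st.ax[:-1], fs.ax]),
        ay=np.concatenate([st.ay[:-1], fs.ay]),
        provenance="com")
    inrun_shifted = PhaseResult(
        TrajectorySeries(t_in, st.x, st.y, vx=st.vx, vy=st.vy,
                         ax=st.ax, ay=st.ay, provenance="com"),
        inrun.forces, s=inrun.s)
    distance = hill.distance_along_profile(x_land)
    return JumpResult(inrun_shifted, flight, com, edge_speed,
                      x_land, t_land, distance)


# -- pose synthesis ---------------------------------------------------------


@dataclass
class PoseProfile:
    """Smooth knee/hip/angle-of-attack time courses, crouch -> flight.

    Each angle follows a logistic transition centred ``t_mid`` seconds
    after take-off with time constant ``tau``.  Angles in radians.
    """

    theta_crouch: float = 1.25
    theta_flight: float = 3.00
    gamma_crouch: float = 0.85
    gamma_flight: float = 2.95
    psi_crouch: float = 0.95
    psi_flight: float = 0.55
    t_mid: float = 0.18
    tau: float = 0.12

    def _logistic(self, t, a, b):
        t = np.asarray(t, dtype=float)
        return a + (b - a) / (1.0 + np.exp(-(t - self.t_mid) / self.tau))

    def theta(self, t):
        return self._logistic(t, self.theta_crouch, self.theta_flight)

    def gamma(self, t):
        return self._logistic(t, self.gamma_crouch, self.gamma_flight)

    def psi(self, t):
        return self._logistic(t, self.psi_crouch, self.psi_flight)


def synthesize_pose(com: TrajectorySeries, pose: PoseProfile,
                    model: SegmentModel, rate_hz: float = 60.0,
                    t0: float | None = None,
                    t1: float | None = None) -> LandmarkSeries:
    """Emit sagittal landmark frames realising the requested angle profiles.

    The ankle-knee-hip-shoulder chain realises theta and gamma exactly and
    is oriented so the ankle->shoulder vector makes the requested angle
    psi with the CoM velocity (body rotated toward the up side).  Arm,
    neck and head ride on the trunk with fixed offsets.  Each frame is
    rigidly translated so the segment-model CoM (incl. equipment)
    coincides with the interpolated input CoM.
    """
    if com.vx is None:
        raise ValueError("CoM series must carry velocity")
    lengths = {}
    for seg in model.segments:
        lengths[seg.name] = seg.reference_length_m
    L_sh = lengths["shank_plus_feet"] if "shank_plus_feet" in lengths else lengths["shank"]
    L_th = lengths["thigh"]
    L_tr = lengths["trunk"]
    L_hd = lengths.get("head_neck", 0.22)
    L_ua = lengths.get("upper_arm", 0.28)
    L_fa = lengths.get("forearm_hand", 0.27)

    t0 = com.t[0] if t0 is None else max(t0, com.t[0])
    t1 = com.t[-1] if t1 is None else min(t1, com.t[-1])
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    tt = t0 + np.arange(n) / rate_hz
    cs_x = CubicSpline(com.t, com.x)
    cs_y = CubicSpline(com.t, com.y)
    cs_vx = CubicSpline(com.t, com.vx)
    cs_vy = CubicSpline(com.t, com.vy)

    th = pose.theta(tt)
    ga = pose.gamma(tt)
    ps = pose.psi(tt)
    if np.any(th <= 0) or np.any(th > np.pi) or np.any(ga <= 0) or np.any(ga > np.pi):
        raise ValueError("unreachable angle combination: theta/gamma must be in (0, pi]")

    pts = {k: np.empty((n, 2)) for k in
           ("ankle", "knee", "hip", "shoulder", "upper_chest", "upper_neck",
            "head_top", "elbow", "wrist")}
    for i in range(n):
        a1 = 0.0
        a2 = a1 + (np.pi - th[i])
        a3 = a2 - (np.pi - ga[i])
        ankle = np.zeros(2)
        knee = ankle + L_sh * np.array([np.cos(a1), np.sin(a1)])
        hip = knee + L_th * np.array([np.cos(a2), np.sin(a2)])
        shoulder = hip + L_tr * np.array([np.cos(a3), np.sin(a3)])
        chi = np.arctan2(*(shoulder - ankle)[::-1])
        vel = np.array([cs_vx(tt[i]), cs_vy(tt[i])])
        rot = np.arctan2(vel[1], vel[0]) + ps[i] - chi
        c, s = np.cos(rot), np.sin(rot)
        R = np.array([[c, -s], [s, c]])
        ankle, knee, hip, shoulder = (R @ p for p in (ankle, knee, hip, shoulder))
        trunk_dir = (shoulder - hip) / np.linalg.norm(shoulder - hip)
        frame = {
            "ankle": ankle, "knee": knee, "hip": hip, "shoulder": shoulder,
            "upper_chest": hip + 0.78 * L_tr * trunk_dir,
            "upper_neck": shoulder + 0.05 * trunk_dir,
            "head_top": shoulder + (0.05 + L_hd) * trunk_dir,
            "elbow": shoulder - L_ua * trunk_dir,
            "wrist": shoulder - (L_ua + L_fa) * trunk_dir,
        }
        com_frame = compute_com(frame, model)
        target = np.array([cs_x(tt[i]), cs_y(tt[i])])
        shift = target - com_frame
        for k in pts:
            pts[k][i] = frame[k] + shift
    return LandmarkSeries(tt, pts, calibrated=True, rate_hz=rate_hz)


# -- sensor sampling --------------------------------------------------------


def sample_sensors(t: np.ndarray, values: np.ndarray, rate_hz: float,
                   noise_sd: float, seed: int,
                   t0: float | None = None,
                   t1: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Resample a truth series onto a sensor clock and add Gaussian noise.

    Cubic interpolation onto a uniform clock at ``rate_hz`` over
    [t0, t1] (defaulting to the source support), then i.i.d. N(0,
    noise_sd^2) per coordinate.  Deterministic for a fixed seed.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(t, float)
    values = np.asarray(values, float)
    lo = t[0] if t0 is None else t0
    hi = t[-1] if t1 is None else t1
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValueError("requested window outside the series support")
    n = int(np.floor((hi - lo) * rate_hz)) + 1
    tt = lo + np.arange(n) / rate_hz
    cs = CubicSpline(t, values)
    out = cs(tt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return tt, out


def sample_trajectory_sensor(series: TrajectorySeries, rate_hz: float,
                             noise_sd: float, seed: int,
                             provenance: str = "antenna",
                             t0: float | None = None,
                             t1: float | None = None) -> TrajectorySeries:
    """Noisy position-only sensor stream (e.g. 50 Hz dGNSS antenna)."""
    tt, xy = sample_sensors(series.t, np.column_stack([series.x, series.y]),
                            rate_hz, noise_sd, seed, t0=t0, t1=t1)
    return TrajectorySeries(tt, xy[:, 0], xy[:, 1], provenance=provenance,
                            rate_hz=rate_hz)


def sample_landmark_sensor(frames: LandmarkSeries, rate_hz: float,
                           noise_sd: float, seed: int) -> LandmarkSeries:
    """Noisy landmark stream at camera rate (noise i.i.d. per coordinate)."""
    rng = np.random.default_rng(seed)
    names = sorted(frames.points)
    stacked = np.concatenate([frames.points[k] for k in names], axis=1)
    tt, vals = sample_sensors(frames.t, stacked, rate_hz, 0.0, seed)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    pts = {k: vals[:, 2 * i:2 * i + 2] for i, k in enumerate(names)}
    return LandmarkSeries(tt, pts, calibrated=frames.calibrated,
                          rate_hz=rate_hz)
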