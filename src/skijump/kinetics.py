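"""Point-mass inverse dynamics along a jump trajectory.

From twice-differentiated position data, the total non-gravitational force
on the jumper is decomposed in the motion frame (axes parallel and
perpendicular to the velocity) into a braking force Fb and a perpendicular
force Fp.  In the in-run Fb = drag + ski friction and Fp = normal force +
lift; once airborne the contact forces vanish, so Fb = drag and Fp = lift,
which lets the drag area CDA = FD / (0.5 rho v^2) be read off directly.

Sign convention: the raw along-motion component of the non-gravitational
force, m*ax*cos(phi) + m*(ay+g)*sin(phi), is negative for resistive
forces; ``braking_force`` negates it so that a force opposing motion is
reported positive, matching how braking forces are plotted.  The
perpendicular component is positive toward the up-normal as printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

G_DEFAULT = 9.81
#: specific gas constant of dry air, J/(kg K)
R_DRY_AIR = 287.05


def motion_angle(vx, vy):
    """Angle phi of the velocity vector, four-quadrant (rad); phi < 0 descending."""
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if np.any((vx == 0) & (vy == 0)):
        raise ValueError("motion angle undefined at zero velocity")
    return np.arctan2(vy, vx)


def rotate_to_motion_frame(vec, phi):
    """Rotate a 2D vector (or stack) into the motion frame.

    Applies [[cos phi, sin phi], [-sin phi, cos phi]]; for the velocity
    vector itself this yields (|v|, 0).
    """
    vec = np.asarray(vec, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    x, y = vec[..., 0], vec[..., 1]
    return np.stack([c * x + s * y, -s * x + c * y], axis=-1)


def braking_force(m, ax, ay, phi, g=G_DEFAULT):
    """Braking force Fb (N), positive opposing motion.

    Magnitude of the non-gravitational force component parallel to the
    velocity: the negated along-motion projection of m*(a - g_vec).
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    return -(m * ax * np.cos(phi) + m * (ay + g) * np.sin(phi))


def perpendicular_force(m, ax, ay, phi, g=G_DEFAULT):
    """Perpendicular force Fp (N), positive toward the up-normal of motion."""
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    return -m * ax * np.sin(phi) + m * (ay + g) * np.cos(phi)


def normal_force_model(m, phi, v, r, g=G_DEFAULT):
    """Track normal force FN = m (g cos(phi) + v^2 / r), incl. centripetal term.

    ``r`` is the local curvature radius; ``np.inf`` denotes a straight
    section (FN = m g cos phi).
    """
    if np.any(np.asarray(r) <= 0):
        raise ValueError("curvature radius must be positive (inf for straight)")
    v = np.asarray(v, dtype=float)
    return m * (g * np.cos(phi) + v ** 2 / r)


def drag_force(rho, v, cda):
    """Aerodynamic drag FD = 1/2 rho v^2 CDA (N)."""
    v = np.asarray(v, dtype=float)
    return 0.5 * rho * v ** 2 * cda


def lift_force(rho, v, cla):
    """Aerodynamic lift FL = 1/2 rho v^2 CLA (N)."""
    v = np.asarray(v, dtype=float)
    return 0.5 * rho * v ** 2 * cla


def estimate_drag_area(Fb, rho, v, v_min=5.0):
    """Invert the drag law: CDA = 2 Fb / (rho v^2), m^2.

    Valid in flight where the braking force is pure drag (ski friction
    neglected in-run, so there the estimate is an upper bound).  Entries
    with v below ``v_min`` or Fb <= 0 are flagged NaN rather than returned:
    near take-off brief negative apparent drag occurs and the inversion
    blows up at low speed.
    """
    Fb = np.asarray(Fb, dtype=float)
    v = np.asarray(v, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cda = 2.0 * Fb / (rho * v ** 2)
    return np.where((v >= v_min) & (Fb > 0), cda, np.nan)


def window_area(F, v, rho):
    """Aerodynamic area from window averages: 2 <F> / (rho <v^2>), m^2.

    Averaging force and speed separately before inverting keeps the
    estimate unbiased under zero-mean acceleration noise, unlike the mean
    of pointwise :func:`estimate_drag_area` values (whose positivity mask
    would clip the noise distribution).
    """
    F = np.asarray(F, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(2.0 * np.nanmean(F) / (rho * np.nanmean(v ** 2)))


def lift_to_drag(FL, FD, eps=1e-9):
    """Lift-to-drag ratio FL/FD; NaN-flagged where FD <= eps (not raised)."""
    FL = np.asarray(FL, dtype=float)
    FD = np.asarray(FD, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = FL / FD
    return np.where(FD > eps, ratio, np.nan)


def ms_to_kmh(v):
    """Convert speed from m/s to km/h (factor 3.6 exactly)."""
    return np.asarray(v, dtype=float) * 3.6


def air_density(pressure_kpa=101.325, temperature_c=15.0):
    """Dry-air ideal-gas density rho = P / (R T), kg/m^3.

    The standard-atmosphere reference (101.325 kPa at 15 C) gives 1.225.
    """
    t_k = temperature_c + 273.15
    if t_k <= 0:
        raise ValueError("temperature below absolute zero")
    return pressure_kpa * 1000.0 / (R_DRY_AIR * t_k)


@dataclass
class KineticsSeries:
    """Force time series derived from one trajectory.

    In flight FD = Fb and FL = Fp pointwise; the drag-area and
    lift-to-drag channels are NaN where undefined (negative apparent drag,
    low speed).
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    Fb: np.ndarray
    Fp: np.ndarray
    FD: np.ndarray
    FL: np.ndarray
    ld_ratio: np.ndarray
    cda: np.ndarray


def kinetics_from_trajectory(traj, m, rho, g=G_DEFAULT,
                             v_min=5.0) -> KineticsSeries:
    """Full inverse-dynamics pass over a differentiated trajectory.

    ``traj`` must expose t, x, vx, vy, ax, ay arrays.  Braking and
    perpendicular force are always computed; the drag/lift/CDA channels
    are the airborne reading of the same components.
    """
    phi = motion_angle(traj.vx, traj.vy)
    v = np.hypot(traj.vx, traj.vy)
    Fb = braking_force(m, traj.ax, traj.ay, phi, g)
    Fp = perpendicular_force(m, traj.ax, traj.ay, phi, g)
    cda = estimate_drag_area(Fb, rho, v, v_min=v_min)
    return KineticsSeries(
        t=np.asarray(traj.t, float), x=np.asarray(traj.x, float), v=v,
        phi=phi, Fb=Fb, Fp=Fp, FD=Fb.copy(), FL=Fp.copy(),
        ld_ratio=lift_to_drag(Fp, Fb), cda=cda,
    )
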