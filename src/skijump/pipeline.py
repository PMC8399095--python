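"""End-to-end workflows tying the modules together.

* :func:`process_position_stream` — the shared raw-position pipeline:
  zero-phase low-pass, differentiate to velocity, re-filter, differentiate
  to acceleration.
* :func:`run_part1` — method comparison: n synthetic jumps observed by a
  50 Hz antenna-like sensor and a 60 Hz camera-like sensor, head-point
  streams compared on a common [-5, 20] m grid (MAE per 5 m + SPM).
* :func:`run_part2` — case study: two jumps differing by start gate,
  phase-routed analysis (in-run -65..0 m and flight 0..90 m from the
  antenna stream; take-off -5..20 m from the pose stream) plus a scored
  points decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import kinetics as kin
from .body import SegmentModel, angle_series, com_series
from .hill import HillProfile
from .series import LandmarkSeries, TrajectorySeries
from .signals import FilterSpec, differentiate, lowpass_zero_phase, resample_to_grid
from .simulate import (JumpResult, PoseProfile, SimulationConfig,
                       sample_landmark_sensor, sample_trajectory_sensor,
                       simulate_jump, synthesize_pose)
from .stats import MAETable, SPMResult, mae_by_phase, paired_difference, spm_paired_ttest

#: variables compared between the two measurement streams
COMPARE_VARS = ("y", "vx", "vy", "ax", "ay")


def process_position_stream(series: TrajectorySeries,
                            spec: FilterSpec = FilterSpec()) -> TrajectorySeries:
    """Filter raw positions and derive velocity and acceleration.

    The low-pass is applied to the raw positions, again to the velocities
    before the second differentiation; each stream is processed at its
    native rate.
    """
    rate = series.rate_hz
    if rate is None:
        raise ValueError("series must be uniformly sampled")
    pos = np.column_stack([series.x, series.y])
    pos_f = lowpass_zero_phase(pos, rate, spec)
    vel = differentiate(pos_f, rate)
    vel_f = lowpass_zero_phase(vel, rate, spec)
    acc = differentiate(vel_f, rate)
    return TrajectorySeries(series.t, pos_f[:, 0], pos_f[:, 1],
                            vx=vel_f[:, 0], vy=vel_f[:, 1],
                            ax=acc[:, 0], ay=acc[:, 1],
                            provenance=series.provenance, rate_hz=rate)


def time_at_x(series: TrajectorySeries, x: float) -> float:
    """Time at which a (monotone-in-x) series crosses horizontal position x."""
    return float(np.interp(x, series.x, series.t))


def _grid_values(proc: TrajectorySeries, grid: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for var in COMPARE_VARS:
        out[var] = resample_to_grid(proc.x, getattr(proc, var), grid)
    return out


@dataclass
class Part1Result:
    grid: np.ndarray
    mae: dict[str, MAETable]
    spm: dict[str, SPMResult]
    n_jumps: int

    def mae_frame(self):
        import pandas as pd
        rows = {}
        first = next(iter(self.mae.values()))
        cols = [f"{lo:g}-{hi:g}" for lo, hi in first.bins]
        for var, table in self.mae.items():
            rows[var] = table.mae
        return pd.DataFrame(rows, index=cols).T


def simulate_observed_jump(cfg: SimulationConfig, hill: HillProfile,
                           pose: PoseProfile, model: SegmentModel,
                           seed: int,
                           window_x: tuple[float, float] = (-5.0, 20.0),
                           margin_s: float = 0.9,
                           gnss_rate: float = 50.0, gnss_sd: float = 0.05,
                           cam_rate: float = 60.0, cam_sd: float = 0.01,
                           truth_rate: float = 200.0):
    """One synthetic jump with both sensor streams over an x window.

    Returns ``(jump, head_truth, gnss_stream, cam_frames)`` where the
    head truth is the head-top landmark of the synthesised pose stream
    (the antenna sits on the helmet, so both sensors observe this point).
    """
    jump = simulate_jump(cfg, hill)
    t0 = time_at_x(jump.com, window_x[0]) - margin_s
    t1 = time_at_x(jump.com, window_x[1]) + margin_s
    t0 = max(t0, jump.com.t[0])
    t1 = min(t1, jump.com.t[-1])
    frames = synthesize_pose(jump.com, pose, model, rate_hz=truth_rate,
                             t0=t0, t1=t1)
    head = frames.points["head_top"]
    head_truth = TrajectorySeries(frames.t, head[:, 0], head[:, 1],
                                  provenance="head")
    gnss = sample_trajectory_sensor(head_truth, gnss_rate, gnss_sd,
                                    seed=seed, provenance="antenna")
    cam = sample_landmark_sensor(frames, cam_rate, cam_sd, seed=seed + 1)
    return jump, head_truth, gnss, cam


def run_part1(hill: HillProfile, base_cfg: SimulationConfig,
              pose: PoseProfile, model: SegmentModel,
              n_jumps: int = 16, seed: int = 0,
              grid_step: float = 0.1,
              window_x: tuple[float, float] = (-5.0, 20.0),
              alpha: float = 0.05) -> Part1Result:
    """Method comparison on n synthetic jumps.

    Jump-to-jump variation comes from jittered take-off impulse and
    aerodynamic areas; both sensors observe the head-top point and their
    processed streams are differenced on the common x grid.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(window_x[0], window_x[1] + grid_step / 2, grid_step)
    a_rows = {v: [] for v in COMPARE_VARS}
    b_rows = {v: [] for v in COMPARE_VARS}
    for j in range(n_jumps):
        cfg = replace(base_cfg,
                      takeoff_impulse_vperp=base_cfg.takeoff_impulse_vperp
                      + rng.normal(0.0, 0.1),
                      cda_flight=float(_scalar(base_cfg.cda_flight)
                                       * (1 + rng.normal(0, 0.03))),
                      cla_flight=float(_scalar(base_cfg.cla_flight)
                                       * (1 + rng.normal(0, 0.03))),
                      seed=seed + 1000 + j)
        _, _, gnss, cam = simulate_observed_jump(
            cfg, hill, pose, model, seed=int(rng.integers(2 ** 31)),
            window_x=window_x)
        proc_a = process_position_stream(gnss)
        head = cam.points["head_top"]
        cam_head = TrajectorySeries(cam.t, head[:, 0], head[:, 1],
                                    provenance="head", rate_hz=cam.rate_hz)
        proc_b = process_position_stream(cam_head)
        ga = _grid_values(proc_a, grid)
        gb = _grid_values(proc_b, grid)
        for v in COMPARE_VARS:
            a_rows[v].append(ga[v])
            b_rows[v].append(gb[v])
    mae: dict[str, MAETable] = {}
    spm: dict[str, SPMResult] = {}
    for v in COMPARE_VARS:
        diffs = paired_difference(np.array(a_rows[v]), np.array(b_rows[v]),
                                  grid, variable=v)
        mae[v] = mae_by_phase(diffs, start=window_x[0], stop=window_x[1])
        spm[v] = spm_paired_ttest(diffs, alpha=alpha)
    return Part1Result(grid, mae, spm, n_jumps)


def _scalar(value) -> float:
    return float(value(0.0)) if callable(value) else float(value)


def _xw(values: np.ndarray, x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return values[(x >= lo) & (x <= hi)]


def _interp_finite(xq: float, x: np.ndarray, y: np.ndarray) -> float:
    good = np.isfinite(y)
    return float(np.interp(xq, x[good], y[good]))


def analyze_phase(proc: TrajectorySeries, mass: float, rho: float,
                  x_window: tuple[float, float]) -> kin.KineticsSeries:
    """Inverse dynamics of a processed stream restricted to an x window."""
    sub = proc.window_x(*x_window)
    return kin.kinetics_from_trajectory(sub, mass, rho)


def run_part2(hill: HillProfile, cfg1: SimulationConfig,
              cfg2: SimulationConfig, pose: PoseProfile,
              model: SegmentModel, seed: int = 0,
              rho: float = 1.225,
              scoring_cfg=None,
              wind1=(0.0,) * 5, wind2=(0.0,) * 5) -> dict:
    """Case-study pipeline for two jumps (typically differing by gate).

    Phase routing: in-run (-65..0 m) and flight (0..90 m) are analysed
    from the 50 Hz antenna-like stream; take-off (-5..20 m) from the
    60 Hz pose stream (CoM + joint angles).  The returned report carries
    per-phase summaries and a scored points decomposition.
    """
    from .scoring import (HillScoringConfig, JumpRecord, compare_jumps,
                          gate_compensation_points, total_score)
    scoring_cfg = scoring_cfg or HillScoringConfig(k_point=hill.k_point_distance)
    report: dict = {"jumps": []}
    records = []
    for i, (cfg, wind) in enumerate(((cfg1, wind1), (cfg2, wind2))):
        jump = simulate_jump(cfg, hill)
        mass = cfg.total_mass
        # full-jump pose truth from slow in-run speeds to landing
        t_start = float(jump.com.t[np.searchsorted(
            np.hypot(jump.com.vx, jump.com.vy), 1.0)])
        frames = synthesize_pose(jump.com, pose, model, rate_hz=120.0,
                                 t0=t_start, t1=jump.com.t[-1])
        head = frames.points["head_top"]
        head_truth = TrajectorySeries(frames.t, head[:, 0], head[:, 1],
                                      provenance="head")
        gnss = sample_trajectory_sensor(head_truth, 50.0, 0.05,
                                        seed=seed + 10 * i, provenance="antenna")
        proc = process_position_stream(gnss)

        x_lo = max(-65.0, proc.x[3]), 0.0
        inrun = analyze_phase(proc, mass, rho, x_lo)
        flight_hi = min(90.0, proc.x[-4])
        flight = analyze_phase(proc, mass, rho, (2.0, flight_hi))
        steady = (flight.t >= flight.t[0] + 0.6)
        cda_mean = kin_window_cda = float(
            2.0 * np.nanmean(flight.Fb[steady])
            / (rho * np.nanmean(flight.v[steady] ** 2)))
        cla_mean = float(2.0 * np.nanmean(flight.Fp[steady])
                         / (rho * np.nanmean(flight.v[steady] ** 2)))

        # take-off window from the pose stream
        t_to0 = time_at_x(jump.com, -5.0) - 0.8
        t_to1 = time_at_x(jump.com, 20.0) + 0.8
        cam = sample_landmark_sensor(
            synthesize_pose(jump.com, pose, model, rate_hz=60.0,
                            t0=max(t_to0, frames.t[0]), t1=t_to1),
            60.0, 0.01, seed=seed + 10 * i + 5)
        com_xy, valid = com_series(cam, model)
        com_traj = TrajectorySeries(cam.t[valid], com_xy[valid, 0],
                                    com_xy[valid, 1], provenance="com",
                                    rate_hz=cam.rate_hz)
        proc_com = process_position_stream(com_traj)
        vel = np.column_stack([proc_com.vx, proc_com.vy])
        angles = angle_series(cam, vel)

        rec = JumpRecord(gate=cfg.gate, distance=jump.distance,
                         wind_measurements=tuple(wind))
        records.append(rec)
        edge_i = int(np.argmin(np.abs(proc.x)))
        report["jumps"].append({
            "gate": cfg.gate,
            "edge_speed_true": jump.edge_speed,
            "edge_speed_measured": float(np.hypot(proc.vx, proc.vy)[edge_i]),
            "landing_x": jump.landing_x,
            "distance": jump.distance,
            "inrun": {
                "v_max": float(np.max(inrun.v)),
                "Fb_mean": float(np.nanmean(inrun.Fb)),
                "Fp_max": float(np.nanmax(inrun.Fp)),
                # window-averaged inversion over the fast late in-run;
                # friction is folded in, so this bounds the true CDA above
                "cda_inrun_estimate": kin.window_area(
                    _xw(inrun.Fb, inrun.x, -45.0, -5.0),
                    _xw(inrun.v, inrun.x, -45.0, -5.0), rho),
            },
            "flight": {
                "FD_mean": float(np.nanmean(flight.Fb[steady])),
                "FL_mean": float(np.nanmean(flight.Fp[steady])),
                "ld_ratio": (cla_mean / cda_mean) if cda_mean > 0 else float("nan"),
                "cda": kin_window_cda,
                "cla": cla_mean,
            },
            "takeoff": {
                "psi_at_10m": _interp_finite(10.0, proc_com.x,
                                             angles.psi[valid]),
                "theta_flight": float(np.nanmedian(angles.theta[-20:])),
                "gamma_flight": float(np.nanmedian(angles.gamma[-20:])),
            },
            "score": total_score(rec, scoring_cfg),
        })
    gate_comp = gate_compensation_points(records[0].gate, records[1].gate,
                                         scoring_cfg)
    decomp = compare_jumps(records[0], records[1], gate_comp, scoring_cfg)
    report["decomposition"] = {
        "raw_difference": decomp.raw_difference,
        "gate_adjustment": decomp.gate_adjustment,
        "adjusted_difference": decomp.adjusted_difference,
    }
    return report
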