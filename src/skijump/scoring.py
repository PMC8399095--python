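"""FIS-style jump scoring: distance points, wind and gate compensation.

Distance points are affine in the distance beyond the K-point (60 points
at K).  Wind compensation weights five along-hill wind measurements into
one effective wind and converts it to points with the hill's wind factor;
a headwind (positive m/s) aids the jumper, so its compensation points are
negative.  Gate compensation converts a start-gate difference into points.
The numeric factors are hill-specific configuration, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class HillScoringConfig:
    k_point: float = 95.0
    meter_value: float = 1.8          # points per metre (typical for HS106)
    wind_factor: float = 8.0          # points per m/s of effective wind
    gate_factor: float = 3.2          # points per gate step
    wind_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self):
        if self.meter_value <= 0:
            raise ValueError("meter_value must be > 0")
        w = np.asarray(self.wind_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("wind weights must be nonnegative and sum to 1")


@dataclass
class JumpRecord:
    """External data of one jump; component points may be supplied directly
    (e.g. from a printed score sheet) or computed from distance/wind."""

    gate: int
    distance: float
    wind_measurements: tuple[float, ...] | None = None
    distance_points: float | None = None
    wind_points: float | None = None

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def distance_points(distance: float, cfg: HillScoringConfig) -> float:
    """60 points at the K-point, +/- meter_value per metre beyond/short."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return 60.0 + (distance - cfg.k_point) * cfg.meter_value


def wind_points(measurements, cfg: HillScoringConfig) -> float:
    """Compensation points for the weighted mean of five wind measurements."""
    w = np.asarray(cfg.wind_weights, float)
    m = np.asarray(measurements, float)
    if m.shape != w.shape:
        raise ValueError(f"expected {len(w)} wind measurements, got {len(m)}")
    return float(-(w @ m) * cfg.wind_factor)


def total_score(record: JumpRecord,
                cfg: HillScoringConfig | None = None) -> float:
    """Distance points plus wind compensation for one jump."""
    dp = record.distance_points
    wp = record.wind_points
    if dp is None:
        if cfg is None:
            raise ValueError("distance_points missing and no config given")
        dp = distance_points(record.distance, cfg)
    if wp is None:
        if record.wind_measurements is None or cfg is None:
            raise ValueError("wind_points missing and not computable")
        wp = wind_points(record.wind_measurements, cfg)
    return dp + wp


@dataclass
class ScoreDecomposition:
    raw_difference: float
    gate_adjustment: float
    adjusted_difference: float


def compare_jumps(rec1: JumpRecord, rec2: JumpRecord,
                  gate_compensation: float,
                  cfg: HillScoringConfig | None = None) -> ScoreDecomposition:
    """Between-jump points decomposition.

    ``raw`` is the plain score difference; subtracting the gate
    compensation isolates the performance difference net of the in-run
    length advantage.
    """
    raw = total_score(rec1, cfg) - total_score(rec2, cfg)
    return ScoreDecomposition(raw, gate_compensation, raw - gate_compensation)


def gate_compensation_points(gate1: int, gate2: int,
                             cfg: HillScoringConfig) -> float:
    """Points credited to the jump started from the higher gate."""
    return (gate1 - gate2) * cfg.gate_factor
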