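"""Filtering, differentiation and frame alignment shared by all streams.

Raw positions from either measurement stream are smoothed with a
fourth-order zero-phase (forward-backward) Butterworth low-pass at 5 Hz,
and the same filter is re-applied before each numerical differentiation
(position -> velocity -> acceleration).  A 2D similarity (Helmert)
transform maps survey/camera frames into the local hill frame with the
origin at the in-run edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification."""

    order: int = 4
    cutoff_hz: float = 5.0

    def sos(self, rate_hz: float):
        nyq = rate_hz / 2.0
        if not 0 < self.cutoff_hz < nyq:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={nyq}) Hz")
        return sps.butter(self.order, self.cutoff_hz / nyq, output="sos")


def lowpass_zero_phase(values: np.ndarray, rate_hz: float,
                       spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero net phase, DC gain 1).

    Endpoints are handled by reflective padding of three filter lengths,
    which keeps transients out of the analysis windows near the series ends.
    Works on 1D series or on (n, k) arrays column-wise along axis 0.
    """
    values = np.asarray(values, dtype=float)
    sos = spec.sos(rate_hz)
    settle = 3 * (2 * spec.order + 1)
    if values.shape[0] <= settle:
        raise ValueError(f"series of length {values.shape[0]} too short to "
                         f"filter (need > {settle} samples)")
    # point-symmetric reflection preserves the boundary slope, which keeps
    # endpoint transients out of the differentiated channels
    return sps.sosfiltfilt(sos, values, axis=0, padtype="odd", padlen=settle)


def differentiate(values: np.ndarray, rate_hz: float) -> np.ndarray:
    """Numerical time derivative: central differences inside, one-sided at ends.

    Output has the same length as the input.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(values, 1.0 / rate_hz, axis=0)


def filtered_derivative(values: np.ndarray, rate_hz: float,
                        spec: FilterSpec = FilterSpec(),
                        order: int = 1) -> np.ndarray:
    """The canonical filter->differentiate chain, applied ``order`` times.

    The filter is re-applied before every differentiation, mirroring how
    raw positions are taken to speeds and then accelerations.
    """
    out = np.asarray(values, dtype=float)
    for _ in range(order):
        out = differentiate(lowpass_zero_phase(out, rate_hz, spec), rate_hz)
    return out


@dataclass(frozen=True)
class SimilarityTransform2D:
    """2D similarity (Helmert) transform: p' = scale * R(rotation) @ p + translation."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform2D":
        inv_t = -np.linalg.solve(self.matrix, np.asarray(self.translation))
        return SimilarityTransform2D(rotation=-self.rotation,
                                     translation=tuple(inv_t),
                                     scale=1.0 / self.scale)


def to_local_frame(points: np.ndarray,
                   transform: SimilarityTransform2D) -> np.ndarray:
    """Map points into the local hill frame through a similarity transform."""
    return transform.apply(points)


def estimate_similarity(src: np.ndarray, dst: np.ndarray,
                        with_scale: bool = True) -> SimilarityTransform2D:
    """Least-squares similarity transform from >= 2 control-point pairs.

    Closed-form (Umeyama/Procrustes) fit of rotation, translation and an
    optional isotropic scale mapping ``src`` onto ``dst``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise ValueError("need matching (n >= 2, 2) control-point arrays")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    ds, dd = src - mu_s, dst - mu_d
    cov = dd.T @ ds / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = (ds ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        scale = 1.0
    rotation = float(np.arctan2(R[1, 0], R[0, 0]))
    translation = mu_d - scale * (R @ mu_s)
    return SimilarityTransform2D(rotation=rotation,
                                 translation=tuple(translation), scale=scale)


def resample_to_grid(x: np.ndarray, values: np.ndarray,
                     grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``values`` (sampled at abscissa ``x``) onto ``grid``.

    ``x`` must be strictly monotone over the window; grid nodes outside the
    support are returned as NaN (flagged missing), never extrapolated.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    d = np.diff(x)
    if np.all(d > 0):
        pass
    elif np.all(d < 0):
        x, values = x[::-1], values[::-1]
    else:
        raise ValueError("abscissa not strictly monotone over the window")
    out = np.interp(grid, x, values, left=np.nan, right=np.nan)
    return out
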