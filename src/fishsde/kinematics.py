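"""Swimming kinematics: linear and angular speed, and the low-pass filter
applied to the distance series before stochastic-model inference.

Speeds are obtained by first-order forward differences of the tracked
positions, so a series of length ``l`` yields ``l - 1`` speed samples.
Angular speed follows the position-vector convention

    omega(t) = (1/dt) * atan2(|det[p(t), p(t+1)]|, p(t) . p(t+1)),

i.e. the absolute angle subtended at the coordinate origin by successive
position vectors, divided by the frame interval. A ``velocity_vectors``
mode applies the same formula to successive velocity vectors instead,
which measures turning of the heading and is translation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal

from .io import TrajectorySeries


class InsufficientDataError(ValueError):
    pass


@dataclass
class KinematicSeries:
    """Per-frame speeds for one fish; omega is the absolute angular speed."""

    v: np.ndarray  # cm/s, length l-1
    omega: np.ndarray  # rad/s, length l-1 (NaN where undefined)
    heading: np.ndarray  # rad, length l-1, from velocity direction


def linear_speed(traj: TrajectorySeries, dt: float) -> np.ndarray:
    """Linear speed v = sqrt(vx^2 + vy^2) from forward differences."""
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 frames for a speed")
    if dt <= 0:
        raise ValueError("dt must be positive")
    vx = np.diff(traj.x) / dt
    vy = np.diff(traj.y) / dt
    return np.hypot(vx, vy)


def _pairwise_angles(px, py, qx, qy, dt):
    """Absolute angle between paired 2-D vectors, per unit time.

    Pairs where either vector is (numerically) zero are undefined and
    returned as NaN rather than zero, so that trial summaries are not
    biased toward rest frames.
    """
    det = px * qy - py * qx
    dot = px * qx + py * qy
    omega = np.arctan2(np.abs(det), dot) / dt
    norm_p = np.hypot(px, py)
    norm_q = np.hypot(qx, qy)
    undefined = (norm_p < 1e-12) | (norm_q < 1e-12)
    omega = np.where(undefined, np.nan, omega)
    return omega


def angular_speed(
    traj: TrajectorySeries,
    dt: float,
    mode: Literal["position_vectors", "velocity_vectors"] = "position_vectors",
) -> np.ndarray:
    """Absolute angular speed of successive position (or velocity) vectors.

    The default ``position_vectors`` mode measures the angle swept at the
    tank centre between consecutive position fixes. ``velocity_vectors``
    measures heading turning from consecutive velocity vectors and needs
    one extra frame.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mode == "position_vectors":
        if len(traj) < 2:
            raise InsufficientDataError("need at least 2 frames")
        return _pairwise_angles(
            traj.x[:-1], traj.y[:-1], traj.x[1:], traj.y[1:], dt
        )
    elif mode == "velocity_vectors":
        if len(traj) < 3:
            raise InsufficientDataError("need at least 3 frames")
        vx = np.diff(traj.x)
        vy = np.diff(traj.y)
        return _pairwise_angles(vx[:-1], vy[:-1], vx[1:], vy[1:], dt)
    raise ValueError(f"unknown mode {mode!r}")


def heading(traj: TrajectorySeries, min_speed: float = 1e-12) -> np.ndarray:
    """Heading angle (rad) from the velocity direction; NaN when at rest."""
    vx = np.diff(traj.x)
    vy = np.diff(traj.y)
    h = np.arctan2(vy, vx)
    return np.where(np.hypot(vx, vy) < min_speed, np.nan, h)


def compute_kinematics(traj: TrajectorySeries, dt: float) -> KinematicSeries:
    return KinematicSeries(
        v=linear_speed(traj, dt),
        omega=angular_speed(traj, dt),
        heading=heading(traj),
    )


def butterworth_lowpass(
    series: np.ndarray,
    order: int = 4,
    cutoff: float = 0.1,
    fs: float = 30.0,
    cutoff_units: Literal["rad/s", "hz"] = "rad/s",
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    ``cutoff`` defaults to 0.1 rad/s (converted to Hz as cutoff/2pi before
    normalisation by the Nyquist frequency). Filtering is applied forward
    and backward (``filtfilt``) so the output has no phase lag, which would
    otherwise contaminate the increment statistics computed downstream.
    Note that 0.1 rad/s at 30 Hz sampling is a very aggressive smoothing;
    the cutoff is a parameter precisely so callers can relax it.
    """
    series = np.asarray(series, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    cutoff_hz = cutoff / (2 * np.pi) if cutoff_units == "rad/s" else cutoff
    nyquist = fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz:.4g} Hz must lie in (0, Nyquist={nyquist:g} Hz)"
        )
    # second-order sections: the (b, a) form of a high-order filter with
    # a cutoff this far below Nyquist is numerically unstable
    sos = signal.butter(order, cutoff_hz / nyquist, btype="low", output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), series.size - 1)
    return signal.sosfiltfilt(sos, series, padlen=padlen)
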