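"""Visual-field metrics for a focal fish among conspecifics.

Two per-frame cues are computed from tracked positions:

* **Opacity** ``O`` — the fraction of the focal fish's *visible* angular
  field occupied by conspecific bodies. Each conspecific is modelled as a
  disc of one body length diameter; the angular interval ("shade") it
  subtends is intersected with the visible field (the full circle minus a
  blind sector of angle ``gamma``), overlapping shades are merged (union,
  not sum), and the resulting measure is normalised by ``2*pi - gamma``.
  ``O = 0`` means an empty field and ``O = 1`` a fully occluded one.

* **Optic flow** ``F`` — the integral over the visible field of the
  absolute angular speed of objects crossing visual rays. Here each
  conspecific's shade moves rigidly at the angular speed of its centre
  bearing, so ``F = sum_j |W_j| * width(shade_j ∩ visible)`` with ``W_j``
  the wrapped displacement of conspecific *j*'s bearing per unit time.
  Rays hitting no conspecific contribute nothing.

Angles live in the focal frame: ``psi = 0`` is the heading direction and
angles are wrapped to (-pi, pi]. Zebrafish have near-panoramic vision with
a blind sector of about 21 degrees; anatomically this sector lies behind
the animal, so the default places it at ``psi = pi``. A ``front`` option
is provided for the alternative convention of a blind interval
``(-gamma/2, gamma/2)`` about ``psi = 0``.

A brute-force ray-casting oracle (:func:`opacity_raycast_oracle`) solves
the ray/circle intersection directly and is used to validate the analytic
interval computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import Trial
from .kinematics import heading as _heading

TWO_PI = 2.0 * math.pi


class OverlapError(ValueError):
    """A conspecific disc overlaps the focal position."""


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.arctan2(np.sin(a), np.cos(a))


@dataclass(frozen=True)
class FocalPose:
    """Position (cm) and heading (rad) of the focal fish."""

    position: tuple[float, float]
    heading: float


@dataclass(frozen=True)
class VisualFieldConfig:
    """Blind angle, conspecific body size and blind-zone placement.

    ``fish_radius`` is half the body length (disc of diameter 1 BL = 3 cm).
    ``gamma`` defaults to 21 degrees.
    """

    gamma: float = math.radians(21.0)
    fish_radius: float = 1.5
    blind_zone_centre: Literal["rear", "front"] = "rear"
    overlap: Literal["error", "clamp"] = "error"

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < TWO_PI:
            raise ValueError("gamma must lie in [0, 2*pi)")
        if self.fish_radius <= 0:
            raise ValueError("fish_radius must be positive")

    @property
    def visible_measure(self) -> float:
        return TWO_PI - self.gamma


@dataclass(frozen=True)
class VisualShade:
    """Angular interval subtended by one conspecific, in the focal frame."""

    centre: float  # rad, wrapped to (-pi, pi]
    half_width: float  # rad, in (0, pi]
    source_id: str = ""

    @property
    def width(self) -> float:
        return min(2.0 * self.half_width, TWO_PI)

    def segments(self) -> list[tuple[float, float]]:
        return _arc_segments(self.centre, self.half_width)


# ---------------------------------------------------------------------------
# interval arithmetic on the circle, using non-wrapping [lo, hi] segments
# within [-pi, pi]


def _arc_segments(centre: float, half_width: float) -> list[tuple[float, float]]:
    """Split an arc (centre ± half_width) at the branch cut into plain
    segments within [-pi, pi]."""
    if half_width >= math.pi:
        return [(-math.pi, math.pi)]
    c = float(wrap_angle(centre))
    lo, hi = c - half_width, c + half_width
    if lo < -math.pi:
        return [(-math.pi, hi), (lo + TWO_PI, math.pi)]
    if hi > math.pi:
        return [(lo, math.pi), (-math.pi, hi - TWO_PI)]
    return [(lo, hi)]


def _merge_segments(
    segments: Iterable[tuple[float, float]]
) -> list[tuple[float, float]]:
    segs = sorted((lo, hi) for lo, hi in segments if hi > lo)
    merged: list[list[float]] = []
    for lo, hi in segs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _intersect_segments(
    a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return _merge_segments(out)


def _measure(segments: Iterable[tuple[float, float]]) -> float:
    return sum(hi - lo for lo, hi in segments)


def visible_segments(cfg: VisualFieldConfig) -> list[tuple[float, float]]:
    """The visible field as segments in the focal frame."""
    if cfg.gamma == 0:
        return [(-math.pi, math.pi)]
    half = cfg.gamma / 2.0
    if cfg.blind_zone_centre == "rear":
        return [(-math.pi + half, math.pi - half)]
    return [(-math.pi, -half), (half, math.pi)]


# ---------------------------------------------------------------------------


def subtended_shade(
    focal: FocalPose,
    other_centre: tuple[float, float],
    radius: float,
    source_id: str = "",
    overlap: Literal["error", "clamp"] = "error",
) -> VisualShade:
    """Angular shade of a disc of ``radius`` at ``other_centre``.

    The shade is centred on the bearing of the disc centre in the focal
    frame with half-width ``asin(radius / d)``. A disc overlapping the
    focal position (``d <= radius``) either raises :class:`OverlapError`
    or, with ``overlap="clamp"``, occludes the full field.
    """
    dx = other_centre[0] - focal.position[0]
    dy = other_centre[1] - focal.position[1]
    d = math.hypot(dx, dy)
    bearing = wrap_angle(math.atan2(dy, dx) - focal.heading)
    if d <= radius:
        if overlap == "clamp":
            return VisualShade(centre=float(bearing), half_width=math.pi,
                               source_id=source_id)
        raise OverlapError(
            f"conspecific {source_id or '?'} at distance {d:.3g} cm overlaps "
            f"the focal fish (radius {radius:g} cm)"
        )
    return VisualShade(
        centre=float(bearing),
        half_width=math.asin(radius / d),
        source_id=source_id,
    )


def opacity(
    focal: FocalPose,
    others: Sequence[tuple[float, float]],
    cfg: VisualFieldConfig | None = None,
) -> float:
    """Fraction of the visible field occluded by conspecific discs."""
    cfg = cfg or VisualFieldConfig()
    if not others:
        return 0.0
    shade_segs: list[tuple[float, float]] = []
    for j, centre in enumerate(others):
        shade = subtended_shade(
            focal, tuple(centre), cfg.fish_radius,
            source_id=str(j), overlap=cfg.overlap,
        )
        shade_segs.extend(shade.segments())
    occluded = _intersect_segments(
        _merge_segments(shade_segs), visible_segments(cfg)
    )
    return _measure(occluded) / cfg.visible_measure


def opacity_raycast_oracle(
    focal: FocalPose,
    others: Sequence[tuple[float, float]],
    cfg: VisualFieldConfig | None = None,
    n_rays: int = 36_000,
) -> float:
    """Discretised opacity by casting uniformly spaced visual rays.

    Each ray is tested against every conspecific disc by solving the
    ray/circle intersection quadratic; the opacity is the fraction of rays
    that are visible and hit at least one disc, normalised as in the
    analytic definition. Converges to :func:`opacity` as ``n_rays`` grows.
    """
    cfg = cfg or VisualFieldConfig()
    if n_rays < 360:
        raise ValueError("n_rays must be >= 360")
    psi = -math.pi + TWO_PI * (np.arange(n_rays) + 0.5) / n_rays
    vis = np.zeros(n_rays, dtype=bool)
    for lo, hi in visible_segments(cfg):
        vis |= (psi >= lo) & (psi <= hi)
    if not others:
        return 0.0
    theta = focal.heading + psi
    ux, uy = np.cos(theta), np.sin(theta)
    hit = np.zeros(n_rays, dtype=bool)
    px, py = focal.position
    r2 = cfg.fish_radius**2
    for cx, cy in others:
        ox, oy = cx - px, cy - py
        if ox * ox + oy * oy <= r2:
            if cfg.overlap == "clamp":
                hit[:] = True
                break
            raise OverlapError("conspecific overlaps the focal fish")
        # |t*u - o|^2 = r^2 with |u| = 1: t^2 - 2 t (u.o) + |o|^2 - r^2 = 0
        b = ux * ox + uy * oy
        disc = b * b - (ox * ox + oy * oy - r2)
        hit |= (disc >= 0) & (b > 0)
    frac = np.count_nonzero(hit & vis) / n_rays
    return frac * TWO_PI / cfg.visible_measure


def optic_flow(
    focal_t: FocalPose,
    focal_t1: FocalPose,
    others_t: Sequence[tuple[float, float]],
    others_t1: Sequence[tuple[float, float]],
    cfg: VisualFieldConfig | None = None,
    dt: float = 1.0 / 30.0,
) -> float:
    """Optic flow (rad^2/s) between two consecutive frames.

    Conspecific lists must be index-aligned (same animal at the same
    position in both lists). Each shade's angular velocity ``W_j`` is the
    wrapped displacement of its centre bearing divided by ``dt``; the
    flow is ``sum_j |W_j| * w_j`` with ``w_j`` the visible shade width
    averaged over the two frames (the symmetric average keeps the metric
    invariant under time reversal, as |W| is even).
    """
    cfg = cfg or VisualFieldConfig()
    if len(others_t) != len(others_t1):
        raise ValueError(
            f"conspecific count mismatch: {len(others_t)} at t vs "
            f"{len(others_t1)} at t+dt"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    vis = visible_segments(cfg)
    total = 0.0
    for j, (c_t, c_t1) in enumerate(zip(others_t, others_t1)):
        shade_t = subtended_shade(
            focal_t, tuple(c_t), cfg.fish_radius, str(j), overlap=cfg.overlap
        )
        shade_t1 = subtended_shade(
            focal_t1, tuple(c_t1), cfg.fish_radius, str(j), overlap=cfg.overlap
        )
        w = wrap_angle(shade_t1.centre - shade_t.centre) / dt
        visible_width = 0.5 * (
            _measure(_intersect_segments(shade_t.segments(), vis))
            + _measure(_intersect_segments(shade_t1.segments(), vis))
        )
        total += abs(w) * visible_width
    return total


@dataclass
class VisualCueSeries:
    """Per-frame opacity and optic flow for one focal fish."""

    fish_id: str
    opacity: np.ndarray  # in [0, 1], length l-1
    optic_flow: np.ndarray  # rad^2/s, >= 0, length l-1


def trial_visual_cues(
    trial: Trial, cfg: VisualFieldConfig | None = None
) -> pd.DataFrame:
    """Opacity and optic flow for every fish and frame of a trial.

    Headings come from the velocity direction, so the last frame (which
    has no velocity) is dropped; frames where the focal fish is at rest
    have undefined heading and yield NaN cues. Returns a tidy frame
    ``trial_id, fish_id, frame, opacity, optic_flow``.
    """
    cfg = cfg or VisualFieldConfig()
    dt = trial.dt
    rows = []
    positions = [f.positions() for f in trial.fish]
    headings = [_heading(f) for f in trial.fish]
    n = trial.n_frames
    for i, focal_traj in enumerate(trial.fish):
        others_idx = [j for j in range(trial.group_size) if j != i]
        o_series = np.full(n - 1, np.nan)
        f_series = np.full(n - 1, np.nan)
        for t in range(n - 1):
            h = headings[i][t]
            if np.isnan(h):
                continue
            focal = FocalPose(tuple(positions[i][t]), float(h))
            others = [tuple(positions[j][t]) for j in others_idx]
            o_series[t] = opacity(focal, others, cfg)
            if t + 1 < n - 1 and not np.isnan(headings[i][t + 1]):
                focal1 = FocalPose(
                    tuple(positions[i][t + 1]), float(headings[i][t + 1])
                )
                others1 = [tuple(positions[j][t + 1]) for j in others_idx]
                f_series[t] = optic_flow(focal, focal1, others, others1, cfg, dt)
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": trial.trial_id,
                    "fish_id": focal_traj.fish_id,
                    "frame": np.arange(n - 1),
                    "opacity": o_series,
                    "optic_flow": f_series,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
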