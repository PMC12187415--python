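"""Synthetic data generators: every input the pipeline needs, no downloads.

Three layers:

* distance paths — Euler–Maruyama paths of a bistable-drift /
  parabolic-diffusion model, one regime per illumination condition;
* trajectory embedding — 2-D group trajectories inside the circular arena
  whose interindividual distance reproduces a given path (exactly for
  dyads, in mean-pairwise distance for triads);
* geometric fixtures — random focal/conspecific poses with ray-cast
  opacity ground truth for regression tests.

The built-in regime parameters are synthetic stand-ins, not estimates
from animal data. They were designed from Kramers escape-rate reasoning
so that a 10-minute trial shows a handful of exploration episodes, with
the dark regime having a weaker tilt toward the close-proximity well, a
lower barrier and a farther exploration well than the bright regime —
hence longer and larger episodes in the dark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .exploration import DistanceSeries
from .io import ArenaConfig, Trial, TrajectorySeries
from .potential import DiffusionParams, PotentialParams, SDEModel
from .simulate import SimConfig, simulate_paths
from .visual import FocalPose, VisualFieldConfig, opacity_raycast_oracle

#: Synthetic illumination regimes (NOT fitted to any experimental data).
#: Bright: stronger tilt toward the close well and a higher barrier —
#: short, small excursions. Dark: weaker tilt, lower barrier, farther
#: exploration well — long, large excursions.
REGIME_POTENTIALS: dict[str, PotentialParams] = {
    "bright": PotentialParams(alpha=-0.15, beta=-0.0028, xl=5.0, xh=15.0),
    "dark": PotentialParams(alpha=-0.04, beta=-0.0012, xl=5.0, xh=17.0),
}

#: Parabolic diffusion, common shape across illumination; triads get a
#: higher amplitude (noisier collective state) than dyads.
REGIME_DIFFUSION: dict[int, DiffusionParams] = {
    2: DiffusionParams(b0=0.80, b1=0.12, b2=-0.006),
    3: DiffusionParams(b0=0.90, b1=0.12, b2=-0.006),
}


def default_model(
    illumination: Literal["bright", "dark"], group_size: int = 2
) -> SDEModel:
    """Built-in synthetic SDE model for one condition."""
    return SDEModel.from_potential(
        REGIME_POTENTIALS[illumination],
        REGIME_DIFFUSION.get(group_size, REGIME_DIFFUSION[2]),
    )


@dataclass
class SynthSpec:
    """Everything needed to generate one condition's synthetic trials."""

    illumination: Literal["bright", "dark"] = "bright"
    group_size: int = 2
    frame_rate: float = 30.0
    n_frames: int = 18_000
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    sigma_pos: float = 0.05  # positional jitter, cm
    heading_smoothness: float = 0.98  # AR(1) memory of the embedding walk
    seed: int = 0
    model: SDEModel | None = None  # None: the built-in regime model

    def __post_init__(self) -> None:
        if self.group_size not in (1, 2, 3):
            raise ValueError("group_size must be 1, 2 or 3")
        if self.n_frames < 2 or self.frame_rate <= 0:
            raise ValueError("invalid sampling spec")
        if not 0 <= self.heading_smoothness < 1:
            raise ValueError("heading_smoothness must be in [0, 1)")

    def resolved_model(self) -> SDEModel:
        return self.model or default_model(self.illumination, self.group_size)


def generate_distance_paths(
    spec: SynthSpec, n_trials: int = 1
) -> list[DistanceSeries]:
    """Seeded distance paths from the spec's regime model."""
    cfg = SimConfig(
        dt=1.0 / spec.frame_rate,
        n_steps=spec.n_frames,
        seed=spec.seed,
        n_trials=n_trials,
    )
    return simulate_paths(spec.resolved_model(), cfg)


def _smooth_angle_walk(rng, n: int, rho: float, step_sd: float) -> np.ndarray:
    """Cumulative angle driven by an AR(1) rate — smooth rotation."""
    rate = np.empty(n)
    rate[0] = rng.normal(0, step_sd)
    eps = rng.normal(0, step_sd * math.sqrt(1 - rho**2), n - 1)
    for k in range(1, n):
        rate[k] = rho * rate[k - 1] + eps[k - 1]
    return np.cumsum(rate)


def _smooth_walk_2d(
    rng, n: int, rho: float, step_sd: float, limit: np.ndarray
) -> np.ndarray:
    """AR(1)-velocity random walk, radially clamped to |c(t)| <= limit(t)."""
    v = np.zeros(2)
    c = np.zeros((n, 2))
    pos = rng.uniform(-1, 1, 2) * limit[0] / 2.0
    sd = step_sd * math.sqrt(1 - rho**2)
    for k in range(n):
        v = rho * v + rng.normal(0, sd, 2)
        pos = pos + v
        r = np.hypot(*pos)
        if r > limit[k]:
            pos = pos * (limit[k] / r)
            v = v * 0.5  # bleed speed at the wall
        c[k] = pos
    return c


def embed_trajectories(x_path: DistanceSeries, spec: SynthSpec) -> Trial:
    """Embed a distance path as 2-D group trajectories in the arena.

    The group centroid follows a smooth bounded random walk; the fish are
    placed around it so that the realised interindividual distance equals
    the path exactly before jitter (dyads: pair distance; triads: mean
    pairwise distance, with a smoothly randomised triangle shape).
    Positional jitter of ``sigma_pos`` cm is then added per fish and
    coordinate.
    """
    if spec.group_size < 2:
        raise ValueError("embedding needs a dyad or triad")
    x = x_path.x
    n = x.size
    R = spec.arena.arena_radius
    margin = spec.arena.body_length / 2.0
    # worst-case centroid-to-fish reach: x/2 for a dyad; for the wobbled
    # triangle (radial factors in [0.7, 1.3]) at most ~0.85 x
    factor = 0.5 if spec.group_size == 2 else 0.85
    reach = factor * x + margin + 3.0 * spec.sigma_pos
    if np.any(reach >= R):
        raise ValueError(
            f"distance path (max {x.max():.1f} cm) does not fit in an arena "
            f"of radius {R:g} cm"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, n, 7]))
    rho = spec.heading_smoothness
    centroid = _smooth_walk_2d(rng, n, rho, step_sd=0.15, limit=R - reach)
    phi = _smooth_angle_walk(rng, n, rho, step_sd=0.02)

    if spec.group_size == 2:
        u = np.column_stack([np.cos(phi), np.sin(phi)])
        offsets = [-0.5 * x[:, None] * u, 0.5 * x[:, None] * u]
    else:
        # triangle: unit directions at phi + 2*pi*i/3 with smooth radial
        # wobble, rescaled so the mean pairwise distance is exactly x
        wobble = [
            1.0 + 0.3 * np.tanh(_smooth_angle_walk(rng, n, rho, 0.005))
            for _ in range(3)
        ]
        dirs = []
        for i in range(3):
            ang = phi + 2.0 * math.pi * i / 3.0
            dirs.append(
                wobble[i][:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
            )
        mean_pair = (
            np.linalg.norm(dirs[0] - dirs[1], axis=1)
            + np.linalg.norm(dirs[0] - dirs[2], axis=1)
            + np.linalg.norm(dirs[1] - dirs[2], axis=1)
        ) / 3.0
        scale = x / mean_pair
        offsets = [scale[:, None] * d for d in dirs]

    fish = []
    for i, off in enumerate(offsets):
        pos = centroid + off
        r = np.linalg.norm(pos, axis=1)
        bad = r > (R - margin)
        if bad.any():  # numerical safety; reach reservation should prevent it
            pos[bad] *= ((R - margin) / r[bad])[:, None]
        jitter = rng.normal(0.0, spec.sigma_pos, pos.shape) if spec.sigma_pos else 0.0
        pos = pos + jitter
        fish.append(
            TrajectorySeries(fish_id=f"f{i + 1}", x=pos[:, 0], y=pos[:, 1])
        )
    return Trial(
        trial_id=x_path.trial_id or f"synth-{spec.seed}",
        illumination=spec.illumination,
        group_size=spec.group_size,
        fish=fish,
        frame_rate=spec.frame_rate,
    )


def generate_trials(spec: SynthSpec, n_trials: int = 1) -> list[Trial]:
    """Distance paths plus embedding, one Trial per path."""
    paths = generate_distance_paths(spec, n_trials)
    trials = []
    for i, p in enumerate(paths):
        sub = replace(spec, seed=spec.seed * 1_000 + i)
        trials.append(embed_trajectories(p, sub))
    return trials


def generate_visual_fixtures(
    n: int,
    seed: int = 0,
    cfg: VisualFieldConfig | None = None,
    arena: ArenaConfig | None = None,
    n_rays: int = 36_000,
) -> list[tuple[FocalPose, list[tuple[float, float]], float]]:
    """Random dyad/triad poses with ray-cast opacity ground truth.

    Conspecifics are kept clear of the focal body (no overlap); each
    fixture carries the oracle opacity at ``n_rays`` rays for use as a
    frozen regression target.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or VisualFieldConfig()
    arena = arena or ArenaConfig()
    rng = np.random.default_rng(seed)
    R = arena.arena_radius - 1.0
    fixtures = []
    while len(fixtures) < n:
        focal = FocalPose(
            position=tuple(rng.uniform(-R / 2, R / 2, 2)),
            heading=float(rng.uniform(-math.pi, math.pi)),
        )
        n_others = int(rng.integers(1, 3))  # dyad or triad scene
        others = []
        for _ in range(n_others):
            for _attempt in range(100):
                p = tuple(rng.uniform(-R, R, 2))
                d = math.hypot(p[0] - focal.position[0], p[1] - focal.position[1])
                if math.hypot(*p) <= R and d > cfg.fish_radius * 1.05:
                    others.append(p)
                    break
        if len(others) != n_others:
            continue
        expected = opacity_raycast_oracle(focal, others, cfg, n_rays=n_rays)
        fixtures.append((focal, others, expected))
    return fixtures
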