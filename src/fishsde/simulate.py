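"""Euler–Maruyama integration and the in-silico experiment harness.

Paths of dx = F(x) dt + G(x) dW are generated with the explicit
Euler–Maruyama scheme

    x[k+1] = x[k] + F(x[k]) dt + G(x[k]) sqrt(dt) z[k],   z[k] ~ N(0, 1),

on a bounded domain with reflecting boundaries by default (the distance
between fish is non-negative and bounded by the tank). One master seed
spawns an independent stream per trial, so any trial is reproducible from
(master seed, trial index) alone.

The in-silico harness replicates the validation design: one identified
model per condition (dyads/triads x bright/dark), the same number of
trials per condition, episode statistics per trial, interquartile-range
outlier exclusion, and a two-way ANOVA on the per-trial means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exploration import DistanceSeries, trial_episode_stats
from .potential import MonostableError, SDEModel, potential_from_drift
from .stats import iqr_outlier_filter, two_way_anova


class IntegrationError(RuntimeError):
    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


@dataclass
class SimConfig:
    """Integration settings; defaults mirror one 10-minute trial at 30 Hz."""

    dt: float = 1.0 / 30.0
    n_steps: int = 18_000
    x0: float | None = None  # None: uniform over [xl, xh] per trial
    domain: tuple[float, float] = (0.0, 57.0)
    boundary: Literal["reflect", "absorb_error"] = "reflect"
    seed: int = 0
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("empty domain")
        if self.x0 is not None and not lo <= self.x0 <= hi:
            raise ValueError("x0 outside domain")


def _default_x0_range(model: SDEModel) -> tuple[float, float]:
    """Initial-condition range: between the wells when the drift is
    bistable, else the middle half of the domain."""
    try:
        p = potential_from_drift(model.drift.coefficients[:4])
        lo = max(p.xl, model.domain[0])
        hi = min(p.xh, model.domain[1])
        if lo < hi:
            return lo, hi
    except (MonostableError, ValueError, IndexError):
        pass
    lo, hi = model.domain
    span = hi - lo
    return lo + 0.25 * span, hi - 0.25 * span


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # fold excursions back; repeat in case a step overshoots both walls
    for _ in range(100):
        out_lo = x < lo
        out_hi = x > hi
        if not (out_lo.any() or out_hi.any()):
            break
        x = np.where(out_lo, 2 * lo - x, x)
        x = np.where(out_hi, 2 * hi - x, x)
    return x


def simulate_paths(model: SDEModel, cfg: SimConfig) -> list[DistanceSeries]:
    """Integrate ``cfg.n_trials`` independent paths of the model.

    Each trial draws its noise (and, when ``cfg.x0`` is None, its initial
    condition) from its own child stream of the master seed.
    """
    lo, hi = cfg.domain
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trials)
    x0_range = _default_x0_range(model) if cfg.x0 is None else None

    # stack per-trial noise so the integration loop is vectorised over trials
    noise = np.empty((cfg.n_trials, cfg.n_steps - 1))
    x = np.empty(cfg.n_trials)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if cfg.x0 is None:
            x[i] = rng.uniform(*x0_range)
        else:
            x[i] = cfg.x0
        noise[i] = rng.standard_normal(cfg.n_steps - 1)

    sqrt_dt = np.sqrt(cfg.dt)
    out = np.empty((cfg.n_trials, cfg.n_steps))
    out[:, 0] = x
    for k in range(cfg.n_steps - 1):
        x = x + model.F(x) * cfg.dt + model.G(x) * sqrt_dt * noise[:, k]
        if not np.isfinite(x).all():
            raise IntegrationError(
                f"non-finite state at step {k + 1}", step=k + 1
            )
        if cfg.boundary == "reflect":
            x = _reflect(x, lo, hi)
        elif ((x < lo) | (x > hi)).any():
            raise IntegrationError(
                f"path left the domain at step {k + 1}", step=k + 1
            )
        out[:, k + 1] = x
    return [
        DistanceSeries(x=out[i], dt=cfg.dt, trial_id=f"sim-{cfg.seed}-{i}")
        for i in range(cfg.n_trials)
    ]


def euler_maruyama(model: SDEModel, cfg: SimConfig) -> DistanceSeries:
    """Integrate a single path (first trial of :func:`simulate_paths`)."""
    return simulate_paths(model, replace(cfg, n_trials=1))[0]


@dataclass
class Condition:
    """One cell of the in-silico design."""

    name: str
    model: SDEModel
    illumination: Literal["bright", "dark"]
    group_size: int
    n_trials: int = 10

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class InSilicoDesign:
    """The four-condition validation design (dyads/triads x bright/dark)."""

    conditions: list[Condition]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design has no conditions")


def run_insilico(
    design: InSilicoDesign,
    cfg: SimConfig | None = None,
    threshold: float = 9.0,
    min_duration: float = 3.0,
) -> pd.DataFrame:
    """Simulate every condition and summarise exploration episodes.

    Returns one row per simulated trial with condition labels, ready for
    outlier exclusion and the two-way ANOVA. Condition seeds are distinct
    children of the master seed.
    """
    cfg = cfg or SimConfig()
    frames = []
    cond_seeds = np.random.SeedSequence(cfg.seed).spawn(len(design.conditions))
    for cond, ss in zip(design.conditions, cond_seeds):
        sub_cfg = replace(
            cfg, n_trials=cond.n_trials, seed=int(ss.generate_state(1)[0] % 2**31)
        )
        paths = simulate_paths(cond.model, sub_cfg)
        for i, p in enumerate(paths):
            p.trial_id = f"{cond.name}-{i}"
        stats = trial_episode_stats(
            [(p, cond.illumination, cond.group_size) for p in paths],
            threshold=threshold,
            min_duration=min_duration,
        )
        stats.insert(0, "condition", cond.name)
        frames.append(stats)
    return pd.concat(frames, ignore_index=True)


def insilico_anova(
    stats: pd.DataFrame,
    response: str = "mean_T",
    exclude_outliers: bool = True,
) -> dict:
    """Two-way ANOVA (illumination x group size) on a per-trial response.

    Trials without episodes are dropped; outliers are excluded per
    condition cell by the interquartile-range rule before the ANOVA. If
    any cell ends up empty the ANOVA is skipped and the report says so.
    """
    df = stats.dropna(subset=[response]).copy()
    if exclude_outliers:
        kept_parts = []
        removed = 0
        for _, cell in df.groupby(["illumination", "group_size"], sort=True):
            kept, rem = iqr_outlier_filter(cell[response].to_numpy())
            removed += len(rem)
            kept_parts.append(cell[cell[response].isin(kept)])
        df = pd.concat(kept_parts, ignore_index=True)
    else:
        removed = 0

    cells = df.groupby(["illumination", "group_size"]).size()
    report: dict = {"response": response, "n_trials": int(len(df)),
                    "n_outliers_removed": int(removed)}
    if len(cells) < 4 or (cells < 1).any():
        report["anova"] = None
        report["skipped"] = "empty design cell (no episodes in a condition)"
        return report
    report["anova"] = two_way_anova(
        df[response].to_numpy(),
        df["illumination"].to_numpy(),
        df["group_size"].astype(str).to_numpy(),
        factor_names=("illumination", "group_size"),
    )
    return report
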