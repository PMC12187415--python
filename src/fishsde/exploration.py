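"""Interindividual distance and intermittent exploration episodes.

The state variable of the whole analysis is the interindividual distance
x(t): the Euclidean distance between two fish, or, for triads, the mean of
the three pairwise distances. An *exploration episode* is a maximal run of
frames with x strictly above a threshold (default 3 body lengths = 9 cm)
that lasts strictly longer than a minimum duration (default 3 s) and is
preceded by at least one frame at or below the threshold — the group must
have been in close proximity before the excursion counts as exploration.
Each episode carries a duration T and an amplitude A (the mean — or,
optionally, median — distance over the episode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Trial


class NotApplicableError(ValueError):
    pass


@dataclass
class DistanceSeries:
    """Interindividual distance x(t) in cm at uniform sampling interval."""

    x: np.ndarray
    dt: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.x.size and not np.isfinite(self.x).all():
            raise ValueError("distance series contains non-finite values")
        if self.x.size and (self.x < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class Episode:
    """One exploration episode over the half-open frame range [start, end)."""

    start_frame: int
    end_frame: int
    duration: float  # s
    amplitude: float  # cm


def interindividual_distance(trial: Trial) -> DistanceSeries:
    """Per-frame interindividual distance of a dyad or triad.

    For triads the three pairwise distances are averaged frame by frame;
    this averaged series is the quantity modelled downstream.
    """
    if trial.group_size < 2:
        raise NotApplicableError(
            "interindividual distance requires at least 2 fish"
        )
    pos = [f.positions() for f in trial.fish]
    pair_dists = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            pair_dists.append(np.linalg.norm(pos[i] - pos[j], axis=1))
    x = np.mean(pair_dists, axis=0)
    return DistanceSeries(x=x, dt=trial.dt, trial_id=trial.trial_id)


def detect_episodes(
    series: DistanceSeries,
    threshold: float = 9.0,
    min_duration: float = 3.0,
    amplitude_mode: Literal["mean", "median"] = "mean",
) -> list[Episode]:
    """Find exploration episodes in a distance series.

    An episode is a maximal run of consecutive frames with x strictly
    above ``threshold`` whose duration (run length times dt) strictly
    exceeds ``min_duration`` and which is preceded, anywhere earlier in
    the trial, by at least one frame with x <= threshold. Both
    inequalities are strict: at 30 Hz a 90-frame (exactly 3.0 s) excursion
    is rejected, a 91-frame one is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = series.x
    if x.size == 0:
        return []
    above = x > threshold
    # run boundaries of the `above` mask
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    episodes = []
    for s, e in zip(starts, ends):
        if s == 0:
            # never in close proximity before this run
            continue
        duration = (e - s) * series.dt
        if duration <= min_duration:
            continue
        episodes.append(
            Episode(
                start_frame=int(s),
                end_frame=int(e),
                duration=duration,
                amplitude=_amplitude(x, s, e, amplitude_mode),
            )
        )
    return episodes


def _amplitude(x: np.ndarray, start: int, end: int, mode: str) -> float:
    if end <= start:
        raise ValueError("empty episode")
    window = x[start:end]
    if mode == "mean":
        return float(np.mean(window))
    if mode == "median":
        return float(np.median(window))
    raise ValueError(f"unknown amplitude mode {mode!r}")


def episode_amplitude(
    series: DistanceSeries,
    episode: Episode,
    mode: Literal["mean", "median"] = "mean",
) -> float:
    """Amplitude of one episode: mean (default) or median distance over it."""
    if not (0 <= episode.start_frame < episode.end_frame <= len(series)):
        raise ValueError("episode outside series bounds")
    return _amplitude(series.x, episode.start_frame, episode.end_frame, mode)


def episodes_table(
    series: DistanceSeries, episodes: Sequence[Episode]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": series.trial_id,
            "start_frame": [e.start_frame for e in episodes],
            "end_frame": [e.end_frame for e in episodes],
            "duration_s": [e.duration for e in episodes],
            "amplitude_cm": [e.amplitude for e in episodes],
        },
        columns=["trial_id", "start_frame", "end_frame", "duration_s",
                 "amplitude_cm"],
    )


def trial_episode_stats(
    entries: Sequence[tuple[DistanceSeries, str, int]],
    threshold: float = 9.0,
    min_duration: float = 3.0,
    amplitude_mode: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Per-trial episode summaries ready for a two-way ANOVA.

    ``entries`` holds (distance series, illumination, group size) per
    trial. Returns one row per trial with the per-trial mean duration and
    amplitude; trials without a single episode carry NaN means and
    ``n_episodes == 0`` so they can be excluded downstream.
    """
    rows = []
    for series, illumination, group_size in entries:
        eps = detect_episodes(series, threshold, min_duration, amplitude_mode)
        rows.append(
            {
                "trial_id": series.trial_id,
                "illumination": illumination,
                "group_size": group_size,
                "mean_T": np.mean([e.duration for e in eps]) if eps else np.nan,
                "mean_A": np.mean([e.amplitude for e in eps]) if eps else np.nan,
                "n_episodes": len(eps),
            }
        )
    return pd.DataFrame(rows)


def stats_from_trials(
    trials: Sequence[Trial],
    threshold: float = 9.0,
    min_duration: float = 3.0,
    amplitude_mode: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Convenience wrapper: episode stats straight from Trial objects."""
    entries = [
        (interindividual_distance(t), t.illumination, t.group_size)
        for t in trials
    ]
    return trial_episode_stats(entries, threshold, min_duration, amplitude_mode)
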