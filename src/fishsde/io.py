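"""Trajectory and results I/O.

Trajectory files are long-format CSV with columns
``trial_id,fish_id,frame,x,y`` (frame is 0-based and gap-free). Positions
are Cartesian, in centimetres, relative to the tank centre; raw pixel
exports are converted with a pixel-to-centimetre ratio. One file may hold
one trial or many.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fishsde")

TRAJECTORY_COLUMNS = ["trial_id", "fish_id", "frame", "x", "y"]


class FormatError(ValueError):
    """A file does not follow the documented CSV dialect."""


class IntegrityError(ValueError):
    """Internally inconsistent data (length mismatches, frame gaps...)."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the circular arena and the tracked animals.

    Defaults describe the experimental setup the package emulates: a 60 cm
    circular tank, adult zebrafish of 3 cm body length, and video
    calibrated at 34.13 pixels per centimetre.
    """

    arena_diameter: float = 60.0  # cm
    body_length: float = 3.0  # cm
    px_per_cm: float = 34.13

    def __post_init__(self) -> None:
        for name in ("arena_diameter", "body_length", "px_per_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def arena_radius(self) -> float:
        return self.arena_diameter / 2.0


@dataclass
class TrajectorySeries:
    """A single fish's 2-D positions, in cm, tank-centred coordinates."""

    fish_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise IntegrityError(
                f"fish {self.fish_id}: x and y must be equal-length 1-D series"
            )
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise IntegrityError(f"fish {self.fish_id}: non-finite positions")

    def __len__(self) -> int:
        return self.x.size

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class Trial:
    """One recording: synchronized trajectories of a group plus metadata."""

    trial_id: str
    illumination: Literal["bright", "dark"]
    group_size: int
    fish: list[TrajectorySeries]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.illumination not in ("bright", "dark"):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        lengths = {len(f) for f in self.fish}
        if len(lengths) > 1:
            raise IntegrityError(
                f"trial {self.trial_id}: fish series lengths differ: {sorted(lengths)}"
            )
        if self.group_size != len(self.fish):
            raise IntegrityError(
                f"trial {self.trial_id}: group_size {self.group_size} != "
                f"{len(self.fish)} trajectories"
            )

    @property
    def n_frames(self) -> int:
        return len(self.fish[0]) if self.fish else 0

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def validate_in_arena(
    trial: Trial, arena: ArenaConfig, tolerance: float = 1.0
) -> None:
    """Raise IntegrityError if any position lies outside the arena radius
    plus ``tolerance`` (cm)."""
    limit = arena.arena_radius + tolerance
    for f in trial.fish:
        r = np.hypot(f.x, f.y)
        if r.size and r.max() > limit:
            raise IntegrityError(
                f"trial {trial.trial_id}, fish {f.fish_id}: position at "
                f"radius {r.max():.2f} cm exceeds arena radius {limit:.2f} cm"
            )


def _trial_from_frame(
    trial_id: str,
    df: pd.DataFrame,
    arena: ArenaConfig,
    units: str,
    metadata: dict,
) -> Trial:
    fish = []
    lengths = {}
    for fish_id, sub in sorted(df.groupby("fish_id", sort=True)):
        frames = sub["frame"].to_numpy()
        if frames.size > 1:
            steps = np.diff(frames)
            if (steps <= 0).any():
                raise IntegrityError(
                    f"trial {trial_id}, fish {fish_id}: non-monotone frame index"
                )
            if (steps != 1).any():
                raise IntegrityError(
                    f"trial {trial_id}, fish {fish_id}: missing frames "
                    f"(largest gap {int(steps.max())})"
                )
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        if units == "px":
            x = x / arena.px_per_cm
            y = y / arena.px_per_cm
        lengths[str(fish_id)] = x.size
        fish.append(TrajectorySeries(fish_id=str(fish_id), x=x, y=y))
    if len(set(lengths.values())) > 1:
        raise IntegrityError(
            f"trial {trial_id}: inconsistent series lengths {lengths}"
        )
    return Trial(
        trial_id=str(trial_id),
        illumination=metadata.get("illumination", "bright"),
        group_size=len(fish),
        fish=fish,
        frame_rate=float(metadata.get("frame_rate", 30.0)),
    )


def read_trials(
    path: str | Path,
    arena: ArenaConfig | None = None,
    units: Literal["cm", "px"] = "cm",
    metadata: dict | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> list[Trial]:
    """Read trajectory CSV(s) into Trial objects with positions in cm.

    Parameters
    ----------
    path
        A CSV file or a directory of CSV files in the long dialect
        ``trial_id,fish_id,frame,x,y``.
    arena
        Geometry used for pixel conversion; defaults to :class:`ArenaConfig`.
    units
        ``"cm"`` (positions stored as-is) or ``"px"`` (divided by
        ``arena.px_per_cm``).
    metadata
        Per-trial metadata, keyed by trial_id, each value a dict with
        ``illumination`` and/or ``frame_rate``; a flat dict applies to all.
    origin
        Coordinate origin to subtract (same units as the file) for raw
        exports not centred on the tank.
    """
    arena = arena or ArenaConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    metadata = metadata or {}

    trials: list[Trial] = []
    for f in files:
        df = pd.read_csv(f)
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"{f}: missing required column(s) {', '.join(missing)}"
            )
        df = df.copy()
        df["x"] = df["x"] - origin[0]
        df["y"] = df["y"] - origin[1]
        for trial_id, sub in df.groupby("trial_id", sort=True):
            meta = metadata.get(str(trial_id), metadata)
            trials.append(_trial_from_frame(str(trial_id), sub, arena, units, meta))
            logger.debug("read trial %s from %s", trial_id, f)
    return trials


def write_trials(trials: Iterable[Trial], path: str | Path) -> None:
    """Write trials back to a single long-format CSV (cm units)."""
    rows = []
    for t in trials:
        for f in t.fish:
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": t.trial_id,
                        "fish_id": f.fish_id,
                        "frame": np.arange(len(f)),
                        "x": f.x,
                        "y": f.y,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=TRAJECTORY_COLUMNS
    )
    out.to_csv(path, index=False, float_format="%.10g")


def cm_to_px(values: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    return np.asarray(values, dtype=float) * arena.px_per_cm


def px_to_cm(values: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    return np.asarray(values, dtype=float) / arena.px_per_cm


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(obj, path: str | Path) -> None:
    """Write a result object to disk; format chosen by extension.

    DataFrames go to ``.csv`` (header always written, so an empty table
    round-trips); dataclasses, dicts and lists go to ``.json``. Floats are
    written with 17 significant digits so a read-back compares equal.
    """
    path = Path(path)
    if path.suffix == ".csv":
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, index=False, float_format="%.17g")
    elif path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2)
    else:
        raise ValueError(f"unsupported results extension: {path.suffix}")


def read_results(path: str | Path):
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unsupported results extension: {path.suffix}")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))
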