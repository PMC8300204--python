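"""Agent-based synthetic flock generator with known ground truth.

The original group-behavior indexes were developed on overhead video of
floor-housed laying hens; no public footage exists, so validation here
runs on a simulated flock in which the quantities the indexes are meant
to recover are dialled in directly:

* ``step_sigma`` — per-second Brownian motility of each bird, the ground
  truth behind the unrest index;
* ``attraction_beta`` — per-second pull toward a fixed attractor (a
  feeder stand-in), the ground truth behind the cluster index.

Each bird follows a first-order discrete-time update at the 1-s cadence
the indexes are defined on::

    x[t+1] = x[t] + beta * (attractor - x[t]) + N(0, sigma^2 I)

reflected at the arena walls so motility is not attenuated near them.
Birds are rendered as filled ellipses with per-frame uniform random
orientation; overlapping birds merge into one connected blob, exactly
what threshold segmentation of real top-view footage produces.

A companion thermal generator emits datalogger-style temperature /
relative-humidity series whose hourly temperature-humidity index lands
in scheduled cold / comfort / heat regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .segmentation import FrameMask

__all__ = [
    "FlockSimConfig",
    "Trajectory",
    "simulate_flock",
    "render_frames",
    "render_grayscale",
    "simulate_thermal",
    "write_mask_pngs",
    "trajectory_to_frame",
    "COMFORT_THI_BANDS",
]


class ConfigurationError(ValueError):
    """Raised when generator settings are internally inconsistent."""


#: Hourly-mean THI bands the thermal generator draws targets from, chosen
#: strictly inside the cold (<59) / comfort / heat (>78) class limits so
#: per-record jitter cannot push an hour across a class boundary.
COMFORT_THI_BANDS: dict[str, tuple[float, float]] = {
    "cold": (50.0, 57.0),
    "comfort": (62.0, 75.0),
    "heat": (79.0, 84.0),
}


@dataclass(frozen=True)
class FlockSimConfig:
    """Generative parameters of one simulated recording.

    Defaults mirror the housed-flock setting the indexes were designed
    for: 20 birds observed on a 352 x 240 px floor at 1 frame/s for a
    15-min recording.

    Parameters
    ----------
    step_sigma:
        Isotropic Gaussian step scale, px per 1-s step.
    attraction_beta:
        Fraction of the distance to ``attractor_xy`` closed per second,
        in [0, 1]. 0 disables the pull entirely.
    init:
        ``"uniform"`` scatters birds uniformly at frame 0;
        ``"stationary"`` (with ``attraction_beta > 0``) draws frame 0
        from the stationary Gaussian of the attraction process, so short
        recordings sample steady-state clustering rather than the
        transient from a uniform release.
    """

    n_birds: int = 20
    arena_h: int = 240
    arena_w: int = 352
    step_sigma: float = 5.0
    attraction_beta: float = 0.0
    attractor_xy: tuple[float, float] = (80.0, 120.0)
    bird_semi_axes: tuple[float, float] = (7.0, 4.0)
    duration_s: int = 900
    fps_out: int = 1
    seed: int = 0
    init: Literal["uniform", "stationary"] = "uniform"

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ConfigurationError("n_birds must be >= 1")
        a, b = self.bird_semi_axes
        if min(a, b) <= 0:
            raise ConfigurationError("bird semi-axes must be positive")
        if self.arena_h < 2 * max(a, b) or self.arena_w < 2 * max(a, b):
            raise ConfigurationError("arena must be at least twice the bird size")
        if not 0 <= self.attraction_beta <= 1:
            raise ConfigurationError("attraction_beta must lie in [0, 1]")
        if self.step_sigma < 0:
            raise ConfigurationError("step_sigma must be >= 0")
        if self.duration_s < 1 or self.fps_out < 1:
            raise ConfigurationError("duration_s and fps_out must be >= 1")
        ax, ay = self.attractor_xy
        if not (0 <= ax < self.arena_w and 0 <= ay < self.arena_h):
            raise ConfigurationError("attractor must lie inside the arena")
        if self.init not in ("uniform", "stationary"):
            raise ConfigurationError(f"unknown init {self.init!r}")

    @property
    def n_frames(self) -> int:
        return self.duration_s * self.fps_out + 1


@dataclass(frozen=True)
class Trajectory:
    """Per-frame bird centers, ``positions[t, bird] = (x, y)`` in px."""

    positions: np.ndarray  # (n_frames, n_birds, 2), float
    timestamps: np.ndarray  # (n_frames,), seconds

    def centers(self, t: int) -> np.ndarray:
        return self.positions[t]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by mirror reflection at both walls."""
    span = hi - lo
    y = np.mod(np.asarray(x, dtype=float) - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _bounds(cfg: FlockSimConfig) -> tuple[float, float, float, float]:
    m = max(cfg.bird_semi_axes)
    return m, cfg.arena_w - 1 - m, m, cfg.arena_h - 1 - m


def simulate_flock(config: FlockSimConfig) -> Trajectory:
    """Simulate bird centers at ``fps_out`` frames/s for ``duration_s`` s.

    The update rule is defined per 1-s step; at finer frame rates the
    per-frame noise and pull are scaled (``sigma * sqrt(dt)`` and
    ``1 - (1-beta)**dt``) so 1-s statistics are preserved. Reproducible
    for a given config and seed.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    lox, hix, loy, hiy = _bounds(cfg)
    dt = 1.0 / cfg.fps_out
    sigma_step = cfg.step_sigma * math.sqrt(dt)
    beta_step = 1.0 - (1.0 - cfg.attraction_beta) ** dt
    attractor = np.asarray(cfg.attractor_xy, dtype=float)

    pos = np.empty((cfg.n_frames, cfg.n_birds, 2), dtype=float)
    if cfg.init == "stationary" and cfg.attraction_beta > 0:
        denom = cfg.attraction_beta * (2.0 - cfg.attraction_beta)
        s = cfg.step_sigma / math.sqrt(denom)
        p0 = attractor + rng.normal(0.0, s, size=(cfg.n_birds, 2))
    else:
        p0 = np.column_stack(
            [
                rng.uniform(lox, hix, size=cfg.n_birds),
                rng.uniform(loy, hiy, size=cfg.n_birds),
            ]
        )
    pos[0, :, 0] = _reflect(p0[:, 0], lox, hix)
    pos[0, :, 1] = _reflect(p0[:, 1], loy, hiy)

    for t in range(1, cfg.n_frames):
        step = rng.normal(0.0, sigma_step, size=(cfg.n_birds, 2))
        new = pos[t - 1] + beta_step * (attractor - pos[t - 1]) + step
        pos[t, :, 0] = _reflect(new[:, 0], lox, hix)
        pos[t, :, 1] = _reflect(new[:, 1], loy, hiy)

    ts = np.arange(cfg.n_frames, dtype=float) * dt
    return Trajectory(positions=pos, timestamps=ts)


def _orientations(cfg: FlockSimConfig, n_frames: int) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 1])
    return rng.uniform(0.0, math.pi, size=(n_frames, cfg.n_birds))


def render_frames(traj: Trajectory, config: FlockSimConfig) -> list[FrameMask]:
    """Rasterize each frame's birds as filled ellipses into binary masks.

    Orientation is uniform random per bird per frame (shape variation
    without a posture model); overlapping birds merge into one blob.
    """
    cfg = config
    n_frames = traj.positions.shape[0]
    angles = _orientations(cfg, n_frames)
    a_major, a_minor = max(cfg.bird_semi_axes), min(cfg.bird_semi_axes)
    masks = []
    for i in range(n_frames):
        img = np.zeros((cfg.arena_h, cfg.arena_w), dtype=bool)
        for j, (x, y) in enumerate(traj.positions[i]):
            rr, cc = _draw_ellipse(
                y, x, a_minor, a_major, shape=img.shape, rotation=angles[i, j]
            )
            img[rr, cc] = True
        masks.append(FrameMask(img, frame_index=i, timestamp_s=float(traj.timestamps[i])))
    return masks


def render_grayscale(
    traj: Trajectory,
    config: FlockSimConfig,
    fg: float = 200.0,
    bg: float = 30.0,
    noise_sd: float = 5.0,
) -> list[np.ndarray]:
    """Grayscale frames (birds bright on a dark floor plus sensor noise).

    Exercises the full crop/filter/threshold segmentation chain; the
    binary masks of :func:`render_frames` bypass it.
    """
    rng = np.random.default_rng([config.seed, 2])
    frames = []
    for m in render_frames(traj, config):
        img = np.where(m.data, fg, bg).astype(float)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        frames.append(np.clip(img, 0, 255))
    return frames


# ---------------------------------------------------------------------------
# thermal series


def simulate_thermal(
    hours: int,
    regime_schedule: Sequence[str],
    seed: int,
    start: str | pd.Timestamp = "2021-01-01 00:00:00",
    records_per_hour: int = 12,
) -> pd.DataFrame:
    """Datalogger-style T/RH series whose hourly THI follows a schedule.

    ``regime_schedule`` assigns each hour a target class among ``cold``,
    ``comfort`` and ``heat``. Twelve records per hour emulate a 5-min
    logging cadence. The hourly THI (computed from hourly-mean T and RH)
    is guaranteed to land inside the scheduled class band.

    Returns a DataFrame with columns ``timestamp, temp_c, rh_pct``.
    """
    if hours < 1:
        raise ConfigurationError("hours must be >= 1")
    if len(regime_schedule) != hours:
        raise ConfigurationError(
            f"schedule length {len(regime_schedule)} != hours {hours}"
        )
    bad = sorted({c for c in regime_schedule if c not in COMFORT_THI_BANDS})
    if bad:
        raise ConfigurationError(f"unknown comfort classes in schedule: {bad}")

    rng = np.random.default_rng([seed, 3])
    start = pd.Timestamp(start)
    step = pd.Timedelta(minutes=60 / records_per_hour)
    rows_t, rows_T, rows_rh = [], [], []
    for h, cls in enumerate(regime_schedule):
        lo, hi = COMFORT_THI_BANDS[cls]
        target = rng.uniform(lo, hi)
        rh = np.clip(rng.normal(65.0, 8.0, size=records_per_hour), 35.0, 95.0)
        thi_vals = target + rng.normal(0.0, 0.3, size=records_per_hour)
        # invert THI = 0.8 T + RH (T - 14.3)/100 + 46.3 for T at each record
        temp = (thi_vals - 46.3 + 0.143 * rh) / (0.8 + rh / 100.0)
        # one linear correction so the hourly-mean THI hits the target exactly
        mean_rh = rh.mean()
        actual = (
            0.8 * temp.mean()
            + mean_rh * (temp.mean() - 14.3) / 100.0
            + 46.3
        )
        temp = temp + (target - actual) / (0.8 + mean_rh / 100.0)
        t0 = start + pd.Timedelta(hours=h)
        rows_t.extend(t0 + np.arange(records_per_hour) * step)
        rows_T.extend(temp)
        rows_rh.extend(rh)
    return pd.DataFrame(
        {"timestamp": rows_t, "temp_c": rows_T, "rh_pct": rows_rh}
    )


# ---------------------------------------------------------------------------
# writers


def write_mask_pngs(masks: Iterable[FrameMask], directory: str | Path) -> list[Path]:
    """Write masks as 8-bit 0/255 PNGs named ``frame_%06d.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in masks:
        p = directory / f"frame_{m.frame_index:06d}.png"
        iio.imwrite(p, (m.data.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def trajectory_to_frame(
    traj: Trajectory, start: str | pd.Timestamp = "2021-01-01 00:00:00"
) -> pd.DataFrame:
    """Long-format trajectory table: timestamp, bird_id, x_px, y_px."""
    start = pd.Timestamp(start)
    n_frames, n_birds, _ = traj.positions.shape
    ts = np.repeat(
        [start + pd.Timedelta(seconds=float(s)) for s in traj.timestamps], n_birds
    )
    return pd.DataFrame(
        {
            "timestamp": ts,
            "bird_id": np.tile(np.arange(n_birds), n_frames),
            "x_px": traj.positions[:, :, 0].ravel(),
            "y_px": traj.positions[:, :, 1].ravel(),
        }
    )
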