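"""End-to-end orchestration: simulate -> segment -> index -> thermal -> report.

A "season" is the synthetic analogue of the observational campaign the
indexes were designed for: three lighting treatments (blue / green /
red) recorded 15 min in the morning and 15 min in the afternoon over
many days, in a shared thermal environment logged every 5 min. The
ground-truth treatment parameters encode the qualitative findings the
statistics should recover: motility (hence unrest) ordered
blue > green > red, and feeder attraction (hence clustering) present
only under red. Blue and green share ``attraction_beta = 0``, making
their spatial configurations distribution-identical — the built-in null
for the cluster comparison.

All intermediates are plain CSV so every stage can be re-run and
inspected on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .flock import (
    ConfigurationError,
    FlockSimConfig,
    render_frames,
    render_grayscale,
    simulate_flock,
    simulate_thermal,
)
from .indexes import CameraGeometry, index_series
from .segmentation import (
    DEFAULT_MIN_AREA,
    FrameMask,
    binarize,
    lowpass,
    measure_sequence,
)
from .thermal import ComfortThresholds, hourly_means, label_recordings
from .stats import aggregate_units, report

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentParams",
    "SeasonConfig",
    "RunConfig",
    "StageError",
    "STUDY_WINDOW_SPLIT",
    "default_window_schedule",
    "season_windows",
    "simulate_recording_indexes",
    "run_synthetic_season",
    "run_pipeline",
]

#: Comfort-class split of the observational campaign's 84 recording
#: windows (thermoneutral / heat / cold); used as the default scheduling
#: proportions for synthetic seasons.
STUDY_WINDOW_SPLIT = {"comfort": 49, "heat": 20, "cold": 15}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class TreatmentParams:
    """Ground-truth dynamics of one lighting treatment."""

    step_sigma: float
    attraction_beta: float


DEFAULT_TREATMENTS: dict[str, TreatmentParams] = {
    "blue": TreatmentParams(step_sigma=8.0, attraction_beta=0.0),
    "green": TreatmentParams(step_sigma=5.0, attraction_beta=0.0),
    "red": TreatmentParams(step_sigma=3.0, attraction_beta=0.005),
}


@dataclass(frozen=True)
class SeasonConfig:
    """Layout of a synthetic observational campaign.

    Two recording windows per day (morning / afternoon) per treatment.
    ``window_schedule`` optionally pins each window's thermal class; by
    default classes are allocated in the campaign's 49:20:15
    comfort:heat:cold proportion and shuffled reproducibly.
    """

    treatments: tuple[tuple[str, TreatmentParams], ...] = tuple(
        DEFAULT_TREATMENTS.items()
    )
    n_days: int = 12
    recording_s: int = 60
    n_birds: int = 20
    arena_h: int = 240
    arena_w: int = 352
    bird_semi_axes: tuple[float, float] = (7.0, 4.0)
    attractor_xy: tuple[float, float] = (80.0, 120.0)
    morning_hour: int = 8
    afternoon_hour: int = 15
    start_date: str = "2021-05-01"
    window_schedule: tuple[str, ...] | None = None
    min_area: int = DEFAULT_MIN_AREA
    seed: int = 0

    @property
    def n_windows(self) -> int:
        return 2 * self.n_days

    def treatment_map(self) -> dict[str, TreatmentParams]:
        return dict(self.treatments)


def default_window_schedule(n_windows: int, seed: int) -> tuple[str, ...]:
    """Window classes in the campaign's proportions, reproducibly shuffled."""
    total = sum(STUDY_WINDOW_SPLIT.values())
    counts = {
        c: int(np.floor(n_windows * k / total)) for c, k in STUDY_WINDOW_SPLIT.items()
    }
    remainders = sorted(
        STUDY_WINDOW_SPLIT,
        key=lambda c: -(n_windows * STUDY_WINDOW_SPLIT[c] / total - counts[c]),
    )
    i = 0
    while sum(counts.values()) < n_windows:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    sched = [c for c in ("comfort", "heat", "cold") for _ in range(counts[c])]
    rng = np.random.default_rng([seed, 4])
    return tuple(np.array(sched)[rng.permutation(n_windows)])


def season_windows(cfg: SeasonConfig) -> pd.DataFrame:
    """Recording-window table: id, date, period, start/end, scheduled class."""
    schedule = cfg.window_schedule or default_window_schedule(cfg.n_windows, cfg.seed)
    if len(schedule) != cfg.n_windows:
        raise ConfigurationError(
            f"window schedule length {len(schedule)} != {cfg.n_windows} windows"
        )
    start0 = pd.Timestamp(cfg.start_date)
    rows = []
    for d in range(cfg.n_days):
        date = start0 + pd.Timedelta(days=d)
        for j, (period, hour) in enumerate(
            (("morning", cfg.morning_hour), ("afternoon", cfg.afternoon_hour))
        ):
            w = 2 * d + j
            start = date + pd.Timedelta(hours=hour)
            rows.append(
                (
                    f"d{d:03d}_{period}",
                    date.date().isoformat(),
                    period,
                    start,
                    start + pd.Timedelta(seconds=cfg.recording_s),
                    schedule[w],
                )
            )
    return pd.DataFrame(
        rows, columns=["recording_id", "date", "period", "start", "end", "scheduled_comfort"]
    )


def _season_thermal(cfg: SeasonConfig, windows: pd.DataFrame) -> pd.DataFrame:
    """Thermal log for the whole campaign honouring the window schedule."""
    hours = cfg.n_days * 24
    schedule = ["comfort"] * hours
    start0 = pd.Timestamp(cfg.start_date)
    for rec in windows.itertuples(index=False):
        h = int((pd.Timestamp(rec.start) - start0) / pd.Timedelta(hours=1))
        schedule[h] = rec.scheduled_comfort
    return simulate_thermal(hours, schedule, seed=cfg.seed, start=start0)


def _child_seed(root: int, index: int) -> int:
    ss = np.random.SeedSequence([root, index])
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_recording_indexes(
    flock_cfg: FlockSimConfig,
    geom: CameraGeometry = CameraGeometry(),
    variant: str = "n_minus_1",
    min_area: int = DEFAULT_MIN_AREA,
    mode: Literal["binary", "grayscale"] = "binary",
    lowpass_sigma: float = 1.0,
    method: str = "otsu",
    polarity: str = "bright_birds",
) -> pd.DataFrame:
    """Simulate one recording and push it through measurement + indexes.

    ``binary`` consumes the rendered masks directly; ``grayscale``
    exercises the full low-pass + threshold segmentation chain on noisy
    grayscale renders.
    """
    traj = simulate_flock(flock_cfg)
    if mode == "binary":
        masks = render_frames(traj, flock_cfg)
    elif mode == "grayscale":
        frames = render_grayscale(traj, flock_cfg)
        masks = [
            binarize(
                lowpass(f, lowpass_sigma),
                method=method,
                polarity=polarity,
                frame_index=i,
                timestamp_s=float(traj.timestamps[i]),
            )
            for i, f in enumerate(frames)
        ]
    else:
        raise ConfigurationError(f"unknown segmentation mode {mode!r}")
    shapes = measure_sequence(masks, min_area=min_area)
    return index_series(
        shapes, geom, frame_hw=(flock_cfg.arena_h, flock_cfg.arena_w), variant=variant
    )


def run_synthetic_season(
    cfg: SeasonConfig,
    geom: CameraGeometry = CameraGeometry(),
    variant: str = "n_minus_1",
    mode: Literal["binary", "grayscale"] = "binary",
    thresholds: ComfortThresholds = ComfortThresholds(),
    rule: str = "thi_only",
    lowpass_sigma: float = 1.0,
) -> dict:
    """Run a whole synthetic campaign; returns every intermediate table.

    Keys of the returned dict: ``windows``, ``thermal``, ``hourly``,
    ``labels``, ``indexes`` (per-frame, with recording metadata) and
    ``units`` (one row per recording x treatment).
    """
    windows = season_windows(cfg)
    thermal = _season_thermal(cfg, windows)
    hourly = hourly_means(thermal)
    labels = label_recordings(windows, hourly, thresholds=thresholds, rule=rule)

    tmap = cfg.treatment_map()
    index_parts = []
    counter = 0
    for trt, params in tmap.items():
        for rec in windows.itertuples(index=False):
            fc = FlockSimConfig(
                n_birds=cfg.n_birds,
                arena_h=cfg.arena_h,
                arena_w=cfg.arena_w,
                step_sigma=params.step_sigma,
                attraction_beta=params.attraction_beta,
                attractor_xy=cfg.attractor_xy,
                bird_semi_axes=cfg.bird_semi_axes,
                duration_s=cfg.recording_s,
                seed=_child_seed(cfg.seed, counter),
                init="stationary" if params.attraction_beta > 0 else "uniform",
            )
            idx = simulate_recording_indexes(
                fc,
                geom=geom,
                variant=variant,
                min_area=cfg.min_area,
                mode=mode,
                lowpass_sigma=lowpass_sigma,
            )
            idx.insert(0, "recording_id", rec.recording_id)
            idx.insert(1, "treatment", trt)
            idx.insert(2, "date", rec.date)
            idx.insert(3, "period", rec.period)
            index_parts.append(idx)
            counter += 1
    indexes = pd.concat(index_parts, ignore_index=True)
    units = aggregate_units(indexes, labels)
    return {
        "windows": windows,
        "thermal": thermal,
        "hourly": hourly,
        "labels": labels,
        "indexes": indexes,
        "units": units,
    }


# ---------------------------------------------------------------------------
# run configuration (YAML) and the full pipeline


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out: str
    seed: int
    season: SeasonConfig
    camera: CameraGeometry
    variant: str = "n_minus_1"
    mode: Literal["binary", "grayscale"] = "grayscale"
    lowpass_sigma: float = 1.0
    thresholds: ComfortThresholds = ComfortThresholds()
    rule: str = "thi_only"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            cam_raw = raw["camera"]
            camera = CameraGeometry(
                height_cm=float(cam_raw["height_cm"]),
                lens_angle_deg=float(cam_raw.get("lens_angle_deg", 60.0)),
                sensor_width_px=int(cam_raw.get("sensor_width_px", 352)),
            )
        except KeyError as e:
            raise ConfigurationError(f"camera configuration missing field {e}") from e
        if "out" not in raw:
            raise ConfigurationError("configuration must name an output directory")
        season_raw = dict(raw.get("season", {}))
        if "treatments" in season_raw:
            season_raw["treatments"] = tuple(
                (name, TreatmentParams(**params))
                for name, params in season_raw["treatments"].items()
            )
        for tup_field in ("bird_semi_axes", "attractor_xy", "window_schedule"):
            if tup_field in season_raw and season_raw[tup_field] is not None:
                season_raw[tup_field] = tuple(season_raw[tup_field])
        seed = int(raw.get("seed", 0))
        season = SeasonConfig(**{"seed": seed, **season_raw})
        thr = ComfortThresholds(**raw.get("thresholds", {}))
        return cls(
            out=str(raw["out"]),
            seed=seed,
            season=season,
            camera=camera,
            variant=str(raw.get("variant", "n_minus_1")),
            mode=raw.get("mode", "grayscale"),
            lowpass_sigma=float(raw.get("lowpass_sigma", 1.0)),
            thresholds=thr,
            rule=str(raw.get("rule", "thi_only")),
            alpha=float(raw.get("alpha", 0.05)),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all intermediates under ``out``.

    Stages: simulate+segment+index, thermal, labels, aggregation,
    report. Any failure is re-raised as :class:`StageError` tagged with
    the stage name. Deterministic for a fixed config and seed.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    season = config.season

    def _stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - tag and propagate
            raise StageError(name, e) from e

    result = _stage(
        "simulate-index",
        lambda: run_synthetic_season(
            season,
            geom=config.camera,
            variant=config.variant,
            mode=config.mode,
            thresholds=config.thresholds,
            rule=config.rule,
            lowpass_sigma=config.lowpass_sigma,
        ),
    )

    def _write():
        result["windows"].to_csv(out / "windows.csv", index=False)
        result["thermal"].to_csv(out / "thermal.csv", index=False)
        result["hourly"].to_csv(out / "hourly.csv", index=False)
        result["labels"].to_csv(out / "labels.csv", index=False)
        result["indexes"].to_csv(out / "indexes.csv", index=False)
        result["units"].to_csv(out / "units.csv", index=False)

    _stage("write-intermediates", _write)

    cfg_echo = {
        "season": {**asdict(season), "treatments": {k: asdict(v) for k, v in season.treatment_map().items()}},
        "camera": asdict(config.camera),
        "variant": config.variant,
        "mode": config.mode,
        "rule": config.rule,
        "thresholds": asdict(config.thresholds),
        "alpha": config.alpha,
    }
    bundle = _stage(
        "report",
        lambda: report(
            result["units"],
            out / "report",
            variant=config.variant,
            alpha=config.alpha,
            seed=config.seed,
            config=cfg_echo,
        ),
    )
    result["report"] = bundle
    return result
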