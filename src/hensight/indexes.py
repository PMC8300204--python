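"""Group-behavior indexes: per-frame cluster index and per-second unrest index.

Both statistics summarize a segmented overhead frame through its blob
morphometry. With ``A`` the mean blob area (px^2), ``P`` the mean blob
perimeter (px), ``D`` the mean pairwise distance between blob centroids
(px), ``nA`` the blob count and ``(h, w)`` the cropped-frame dimensions,
the cluster index of frame ``i`` is::

    CI(i) = 2 * A * sqrt(h^2 + w^2) / (P * D * (nA - 1))      (n_minus_1)
    CI(i) = 2 * A * sqrt(h^2 + w^2) / (P * D * nA)            (n_inverse)

The two variants are the two dimensionally identical readings of the
published denominator, whose typography is ambiguous; results are always
labelled with the variant used, default ``n_minus_1``. Higher values
mean tighter agglomeration.

The unrest index between consecutive frames 1 s apart is the symmetric
Hausdorff distance between the two frames' centroid sets, converted to
centimeters through the camera's ground-sampling factor ``k``::

    UI(i, i-1) = k * max{ dH(F(i), F(i-1)), dH(F(i-1), F(i)) }
    k = 2 * H * tan(alpha / 2) / w_sensor          [cm / px]

with ``H`` the camera height above the floor (cm), ``alpha`` the lens
opening angle and ``w_sensor`` the frame width in px. Higher values mean
more flock movement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .segmentation import Shape

logger = logging.getLogger(__name__)

__all__ = [
    "CameraGeometry",
    "UndefinedTermError",
    "pixel_to_cm_factor",
    "mean_pairwise_distance",
    "cluster_index",
    "directed_hausdorff",
    "unrest_index",
    "index_series",
]

Variant = Literal["n_minus_1", "n_inverse"]


class UndefinedTermError(ValueError):
    """A formula term is undefined for this input (e.g. < 2 centroids)."""


@dataclass(frozen=True)
class CameraGeometry:
    """Overhead-camera geometry yielding the cm-per-px ground scale.

    Defaults are the reference rig: a ceiling camera 150 cm above the
    floor with a 60 degree lens imaging 352 px across.
    """

    height_cm: float = 150.0
    lens_angle_deg: float = 60.0
    sensor_width_px: int = 352

    def __post_init__(self) -> None:
        if self.height_cm < 0:
            raise ValueError("camera height must be >= 0")
        if not 0 < self.lens_angle_deg < 180:
            raise ValueError("lens opening angle must lie in (0, 180) degrees")
        if self.sensor_width_px < 1:
            raise ValueError("sensor width must be >= 1 px")


def pixel_to_cm_factor(geom: CameraGeometry) -> float:
    """Ground-sampling factor ``k = 2 H tan(alpha/2) / w`` in cm/px."""
    half = math.radians(geom.lens_angle_deg) / 2.0
    return 2.0 * geom.height_cm * math.tan(half) / geom.sensor_width_px


def _as_points(pts: Sequence) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = arr.reshape(-1, 2)
    return arr


def mean_pairwise_distance(centroids: Sequence) -> float:
    """Mean Euclidean distance over all unordered centroid pairs."""
    pts = _as_points(centroids)
    if len(pts) < 2:
        raise UndefinedTermError("mean pairwise distance needs >= 2 centroids")
    return float(pdist(pts).mean())


def cluster_index(
    shapes: Sequence[Shape],
    h: int,
    w: int,
    variant: Variant = "n_minus_1",
) -> float:
    """Cluster index of one frame from its blob shapes.

    ``h`` and ``w`` are the dimensions of the cropped frame the shapes
    were measured in. Raises :class:`UndefinedTermError` when a formula
    term is undefined (fewer than 2 blobs); callers mark such frames
    invalid rather than fabricating a value.
    """
    if variant not in ("n_minus_1", "n_inverse"):
        raise ValueError(f"unknown cluster-index variant {variant!r}")
    n = len(shapes)
    if n < 2:
        raise UndefinedTermError(
            "cluster index needs >= 2 blobs (mean pair distance undefined)"
        )
    mean_area = float(np.mean([s.area for s in shapes]))
    mean_perim = float(np.mean([s.perimeter for s in shapes]))
    d_bar = mean_pairwise_distance([s.centroid for s in shapes])
    diag = math.hypot(h, w)
    denom_n = (n - 1) if variant == "n_minus_1" else n
    return 2.0 * mean_area * diag / (mean_perim * d_bar * denom_n)


def directed_hausdorff(A: Sequence, B: Sequence) -> float:
    """``max over a in A of min over b in B`` of the Euclidean distance."""
    a = _as_points(A)
    b = _as_points(B)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedTermError("Hausdorff distance needs non-empty point sets")
    return float(cdist(a, b).min(axis=1).max())


def unrest_index(
    centroids_prev: Sequence,
    centroids_cur: Sequence,
    k: float,
) -> float:
    """Symmetric Hausdorff distance between two centroid sets, in cm."""
    d = max(
        directed_hausdorff(centroids_cur, centroids_prev),
        directed_hausdorff(centroids_prev, centroids_cur),
    )
    return k * d


def index_series(
    shape_table: pd.DataFrame,
    geom: CameraGeometry,
    frame_hw: tuple[int, int],
    variant: Variant = "n_minus_1",
    fps: float = 1.0,
) -> pd.DataFrame:
    """Assemble both index series from a per-frame blob table.

    ``shape_table`` is the output of
    :func:`hensight.segmentation.measure_sequence` (columns frame, ts_s,
    blob_id, area_px2, perimeter_px, cx_px, cy_px), sorted by frame;
    frames absent from the table (no blob survived filtering) are still
    emitted, flagged invalid. The unrest value at frame ``i`` pairs
    frames ``i-1`` and ``i`` of the 1 frame/s stream; a missing or empty
    frame breaks the pair.

    Returns one row per frame: frame, ts_s, cluster_index,
    unrest_index_cm, n_clusters, mean_area_px2, mean_perimeter_px,
    mean_pair_distance_px, cluster_valid, unrest_valid, valid.
    """
    required = {"frame", "blob_id", "area_px2", "perimeter_px", "cx_px", "cy_px"}
    missing = required - set(shape_table.columns)
    if missing:
        raise ValueError(f"shape table lacks columns {sorted(missing)}")
    frames_seen = shape_table["frame"].to_numpy()
    first_seen = pd.unique(frames_seen)
    if len(first_seen) and np.any(np.diff(first_seen) <= 0):
        raise ValueError("shape table must be sorted by frame without duplicates")

    k = pixel_to_cm_factor(geom)
    h, w = frame_hw
    groups = {int(f): g for f, g in shape_table.groupby("frame", sort=True)}
    ts_map = (
        shape_table.groupby("frame")["ts_s"].first().to_dict()
        if "ts_s" in shape_table.columns
        else {}
    )
    if groups:
        f0, f1 = min(groups), max(groups)
    else:
        f0, f1 = 0, -1

    rows = []
    prev_pts: np.ndarray | None = None
    for f in range(f0, f1 + 1):
        g = groups.get(f)
        if g is None or g.empty:
            pts = None
            n = 0
            ci = np.nan
            a_bar = p_bar = d_bar = np.nan
        else:
            pts = g[["cx_px", "cy_px"]].to_numpy(dtype=float)
            n = len(pts)
            a_bar = float(g["area_px2"].mean())
            p_bar = float(g["perimeter_px"].mean())
            shapes = [
                Shape(int(a), int(p), (float(x), float(y)))
                for a, p, x, y in zip(
                    g["area_px2"], g["perimeter_px"], g["cx_px"], g["cy_px"]
                )
            ]
            try:
                d_bar = mean_pairwise_distance(pts)
                ci = cluster_index(shapes, h=h, w=w, variant=variant)
            except UndefinedTermError:
                d_bar = np.nan
                ci = np.nan
        cluster_valid = bool(np.isfinite(ci))

        if prev_pts is not None and pts is not None:
            ui = unrest_index(prev_pts, pts, k)
            unrest_valid = True
        else:
            ui = np.nan
            unrest_valid = False

        rows.append(
            (
                f,
                float(ts_map.get(f, f / fps)),
                ci,
                ui,
                n,
                a_bar,
                p_bar,
                d_bar,
                cluster_valid,
                unrest_valid,
                cluster_valid and (unrest_valid or f == f0),
            )
        )
        prev_pts = pts

    out = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "ts_s",
            "cluster_index",
            "unrest_index_cm",
            "n_clusters",
            "mean_area_px2",
            "mean_perimeter_px",
            "mean_pair_distance_px",
            "cluster_valid",
            "unrest_valid",
            "valid",
        ],
    )
    n_invalid = int((~out["cluster_valid"]).sum())
    if n_invalid:
        logger.info(
            "index_series: %d of %d frames invalid for the cluster index",
            n_invalid,
            len(out),
        )
    return out
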