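"""Frame ingestion and threshold-based segmentation into bird blobs.

Turns raw grayscale overhead frames into per-frame blob measurements
(area, perimeter, centroid) through the chain

    crop to region of interest -> low-pass filter -> binarize -> label

Coordinate convention, used everywhere in this package: origin at the
top-left pixel, ``x`` = column, ``y`` = row, 0-based. A pixel's
coordinates refer to its center.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "RegionOfInterest",
    "FrameMask",
    "Shape",
    "crop_roi",
    "lowpass",
    "binarize",
    "label_components",
    "measure_sequence",
    "read_frames",
    "write_shapes_csv",
    "DEFAULT_MIN_AREA",
]

#: Blobs below this pixel area are treated as segmentation noise and
#: discarded.  ~0.06% of a 352x240 frame; configurable everywhere.
DEFAULT_MIN_AREA = 50


class InputError(ValueError):
    """Raised for invalid frames, polygons or segmentation settings."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Object-free floor polygon inside which all measurements are taken.

    Vertices are ``(x, y)`` pixel coordinates in the frame convention
    above. The polygon is delimited once (on the first frame) and
    replicated for every consecutive frame of a recording.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise InputError("a region of interest needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def full_frame(cls, h: int, w: int) -> "RegionOfInterest":
        return cls(((0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)))

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def rasterize(self, h: int, w: int) -> np.ndarray:
        """Boolean mask of pixels whose centers lie in or on the polygon."""
        poly = self.polygon()
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0 or miny < 0 or maxx > w - 1 or maxy > h - 1:
            raise InputError(
                f"polygon bounds {poly.bounds} exceed frame {h}x{w}"
            )
        xs, ys = np.meshgrid(np.arange(w), np.arange(h))
        inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
        return inside.reshape(h, w)


@dataclass(frozen=True)
class FrameMask:
    """Binary occupancy grid for one segmented frame (foreground = bird)."""

    data: np.ndarray  # bool, shape (h, w)
    frame_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError("mask must be a non-empty 2-D grid")
        object.__setattr__(self, "data", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Shape:
    """One connected blob: a bird or a touching group of birds.

    ``area`` is the foreground pixel count (px^2), ``perimeter`` the
    number of pixel edges between the blob and the background, counting
    hole boundaries (a 10x10 solid square has perimeter 40), and
    ``centroid`` the mean foreground pixel coordinate as ``(x, y)``.
    """

    area: int
    perimeter: int
    centroid: tuple[float, float]


# ---------------------------------------------------------------------------
# pipeline steps


def crop_roi(
    frame: np.ndarray,
    roi: RegionOfInterest,
    background: int | float = 0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Mask out everything outside the ROI and crop to its bounding box.

    Returns ``(cropped, (x_offset, y_offset))``; adding the offset to a
    centroid measured in the crop maps it back to full-frame coordinates.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise InputError("expected a single-channel grayscale frame")
    h, w = frame.shape
    inside = roi.rasterize(h, w)
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    out = np.where(inside, frame, background)[r0:r1, c0:c1]
    return out, (int(c0), int(r0))


def lowpass(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian low-pass with reflective borders; ``sigma_px=0`` is identity."""
    if sigma_px < 0:
        raise InputError("sigma_px must be >= 0")
    frame = np.asarray(frame, dtype=float)
    if sigma_px == 0:
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma=sigma_px, mode="reflect")


def binarize(
    frame: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
    polarity: Literal["bright_birds", "dark_birds"] = "bright_birds",
    frame_index: int = 0,
    timestamp_s: float = 0.0,
) -> FrameMask:
    """Threshold a grayscale frame so that only the birds are foreground.

    ``otsu`` picks the threshold maximizing between-class variance;
    ``fixed`` requires an explicit ``threshold`` in [0, 255]. With
    ``bright_birds`` foreground is strictly above the threshold, with
    ``dark_birds`` at or below it (the exact complement).
    """
    frame = np.asarray(frame)
    if method == "fixed":
        if threshold is None:
            raise InputError("fixed thresholding requires a threshold value")
        if not 0 <= threshold <= 255:
            raise InputError("fixed threshold must lie in [0, 255]")
        thr = float(threshold)
    elif method == "otsu":
        thr = float(threshold_otsu(frame))
    else:
        raise InputError(f"unknown binarization method {method!r}")
    if polarity == "bright_birds":
        mask = frame > thr
    elif polarity == "dark_birds":
        mask = frame <= thr
    else:
        raise InputError(f"unknown polarity {polarity!r}")
    return FrameMask(mask, frame_index=frame_index, timestamp_s=timestamp_s)


def _edge_perimeters(labels: np.ndarray) -> np.ndarray:
    """Per-label count of pixel edges facing a different label or background."""
    nlab = int(labels.max())
    padded = np.pad(labels, 1)
    out = np.zeros(nlab + 1, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        sel = (padded > 0) & (nb != padded)
        out += np.bincount(padded[sel], minlength=nlab + 1)
    return out


def label_components(
    mask: FrameMask | np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[Shape]:
    """Extract 8-connected blobs from a binary mask, dropping specks.

    Components with fewer than ``min_area`` pixels are discarded. An
    empty mask yields an empty list.
    """
    data = mask.data if isinstance(mask, FrameMask) else np.asarray(mask).astype(bool)
    labels = _sk_label(data, connectivity=2)
    if labels.max() == 0:
        return []
    perims = _edge_perimeters(labels)
    shapes = []
    for rp in regionprops(labels):
        if rp.area < min_area:
            continue
        cy, cx = rp.centroid
        shapes.append(
            Shape(
                area=int(rp.area),
                perimeter=int(perims[rp.label]),
                centroid=(float(cx), float(cy)),
            )
        )
    return shapes


# ---------------------------------------------------------------------------
# sequence helpers and I/O


def measure_sequence(
    masks: Iterable[FrameMask],
    min_area: int = DEFAULT_MIN_AREA,
) -> pd.DataFrame:
    """Blob table for a mask sequence.

    Columns: frame, ts_s, blob_id, area_px2, perimeter_px, cx_px, cy_px.
    Frames with no blob surviving the area filter contribute no rows.
    """
    rows = []
    for m in masks:
        for j, s in enumerate(label_components(m, min_area=min_area)):
            rows.append(
                (m.frame_index, m.timestamp_s, j, s.area, s.perimeter, *s.centroid)
            )
    return pd.DataFrame(
        rows,
        columns=["frame", "ts_s", "blob_id", "area_px2", "perimeter_px", "cx_px", "cy_px"],
    )


def _natural_key(path: Path) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", path.name)]


def read_frames(directory: str | Path, pattern: str = "*.png") -> list[np.ndarray]:
    """Read a natural-sorted grayscale frame sequence from a directory."""
    paths = sorted(Path(directory).glob(pattern), key=_natural_key)
    if not paths:
        raise InputError(f"no frames matching {pattern!r} in {directory}")
    frames = []
    for p in paths:
        img = iio.imread(p)
        if img.ndim == 3:  # collapse an RGB(A) export to luminance
            img = img[..., :3].mean(axis=-1)
        frames.append(np.asarray(img))
    return frames


def write_shapes_csv(shapes: pd.DataFrame, path: str | Path) -> None:
    shapes.to_csv(path, index=False)
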