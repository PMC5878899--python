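"""Centroid tracking and dwell-time mapping of per-frame femur masks.

Coordinate convention: x = lateral direction (columns), y = depth
(rows), both in mm with the origin at the ROI's top-left pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CentroidTrack:
    """Per-frame femur centroid trajectory in physical units.

    x, y hold NaN on frames flagged missing.  ``frame_rate`` converts
    frame indices to seconds.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    frame_rate: float = 25.0
    pixel_spacing: float = 0.1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.missing) == n):
            raise ValueError("track arrays must share one length")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.frame_rate

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions; NaN where missing."""
        return np.column_stack([self.x, self.y])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_s": self.times,
                "x_mm": self.x,
                "y_mm": self.y,
                "missing": self.missing.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate: float = 25.0, pixel_spacing: float = 0.1):
        return cls(
            frames=df["frame"].to_numpy(),
            x=df["x_mm"].to_numpy(),
            y=df["y_mm"].to_numpy(),
            missing=df["missing"].to_numpy().astype(bool),
            frame_rate=frame_rate,
            pixel_spacing=pixel_spacing,
        )


def centroid(mask: np.ndarray, pixel_spacing: float = 0.1) -> tuple[float, float]:
    """Centroid (x, y) of a binary mask in mm.

    Arithmetic mean of member-pixel (column, row) indices scaled by the
    pixel spacing.  An empty mask returns (nan, nan) as the missing-value
    marker.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return (float("nan"), float("nan"))
    return (float(cols.mean() * pixel_spacing), float(rows.mean() * pixel_spacing))


def track_from_masks(
    masks,
    pixel_spacing: float = 0.1,
    frame_rate: float = 25.0,
) -> CentroidTrack:
    """Build a :class:`CentroidTrack` from per-frame masks (None = missing)."""
    xs, ys, miss = [], [], []
    for m in masks:
        if m is None or not np.asarray(m).any():
            xs.append(float("nan"))
            ys.append(float("nan"))
            miss.append(True)
        else:
            cx, cy = centroid(m, pixel_spacing)
            xs.append(cx)
            ys.append(cy)
            miss.append(False)
    return CentroidTrack(
        frames=np.arange(len(xs)),
        x=np.array(xs),
        y=np.array(ys),
        missing=np.array(miss),
        frame_rate=frame_rate,
        pixel_spacing=pixel_spacing,
    )


def dwell_map(masks) -> np.ndarray:
    """Per-pixel count of frames in which the mask covers that pixel.

    Missing frames (None) contribute nothing.  All masks must share one
    shape.
    """
    shape = None
    counts = None
    for m in masks:
        if m is None:
            continue
        m = np.asarray(m, dtype=bool)
        if shape is None:
            shape = m.shape
            counts = np.zeros(shape, dtype=np.int64)
        elif m.shape != shape:
            raise ValueError(f"mask shape {m.shape} differs from {shape}")
        counts += m
    if counts is None:
        raise ValueError("no masks provided")
    return counts


def fill_missing(track: CentroidTrack, max_gap: int = 3) -> CentroidTrack:
    """Linearly interpolate interior missing gaps of length <= max_gap.

    Longer gaps (and gaps touching either end of the trial) stay missing
    and are excluded from downstream statistics.
    """
    x = track.x.copy()
    y = track.y.copy()
    missing = track.missing.copy()
    n = len(track)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        gap = j - i
        if 0 < i and j < n and gap <= max_gap:
            for k in range(i, j):
                t = (k - (i - 1)) / (j - (i - 1))
                x[k] = x[i - 1] + t * (x[j] - x[i - 1])
                y[k] = y[i - 1] + t * (y[j] - y[i - 1])
                missing[k] = False
        i = j
    return CentroidTrack(
        frames=track.frames.copy(),
        x=x,
        y=y,
        missing=missing,
        frame_rate=track.frame_rate,
        pixel_spacing=track.pixel_spacing,
    )
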