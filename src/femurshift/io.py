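"""Reading ultrasound frame sequences and torque traces from disk."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


@dataclass
class ImageSequence:
    """Ordered 8-bit grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (n, H, W) uint8
    frame_rate: float = 25.0
    pixel_spacing: float = 0.1

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:  # RGB(A) PNG of a grayscale image
        frame = frame[..., :3].mean(axis=-1).round().astype(np.uint8)
    return frame


def read_frames(
    path: str | Path,
    frame_rate: float = 25.0,
    pixel_spacing: float = 0.1,
) -> ImageSequence:
    """Read a frame sequence from a directory of numbered PNG/TIFF images
    or from a single multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        frames = np.stack([_to_gray(iio.imread(p)) for p in files])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError(f"unsupported frame source: {path} (use a PNG directory or a TIFF)")
    return ImageSequence(frames=frames, frame_rate=frame_rate, pixel_spacing=pixel_spacing)


def read_torque_csv(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    """Read a torque trace (MVC fraction per frame) from a 2-column CSV.

    If the trace length differs from ``n_frames`` it is linearly resampled
    to one sample per frame; a single-sample mismatch is treated as an
    acquisition misalignment and rejected.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("torque CSV needs (frame_index, torque) columns")
    torque = df.iloc[:, 1].to_numpy(dtype=float)
    if n_frames is not None and torque.size != n_frames:
        raise ValueError(
            f"torque trace has {torque.size} samples but the sequence has "
            f"{n_frames} frames"
        )
    return torque


def resample_torque(torque: np.ndarray, n_frames: int) -> np.ndarray:
    """Linearly resample a torque trace to one sample per frame."""
    torque = np.asarray(torque, dtype=float)
    if torque.size == n_frames:
        return torque
    old_t = np.linspace(0.0, 1.0, torque.size)
    new_t = np.linspace(0.0, 1.0, n_frames)
    return np.interp(new_t, old_t, torque)
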