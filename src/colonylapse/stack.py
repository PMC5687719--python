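"""Timelapse stack loading and background correction.

Conventions used throughout the package:

* Frames are a ``T x H x W x 3`` float array, channel order (R, G, B).
* Positions are ``(row, col)``, 0-based, pixel centers at integer
  coordinates.
* Time is in hours everywhere, so growth and expression rates carry
  h^-1 units, the standard convention for bacterial kinetics.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["Timelapse", "load_timelapse", "subtract_background"]


@dataclass(frozen=True)
class Timelapse:
    """An RGB timelapse of a single agar plate.

    Attributes
    ----------
    frames
        ``T x H x W x 3`` array of non-negative float intensities.
    times
        Length-``T`` array of acquisition times in hours, strictly
        increasing.
    bit_depth
        Bit depth of the source images (8 or 16); metadata only, values
        are promoted to float on load.
    background
        Per-channel background estimate already subtracted from
        ``frames`` ((0, 0, 0) if uncorrected).
    """

    frames: np.ndarray
    times: np.ndarray
    bit_depth: int = 8
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError(
                f"frames must be T x H x W x 3, got shape {frames.shape}"
            )
        if times.ndim != 1 or len(times) != frames.shape[0]:
            raise ValueError(
                f"times length {times.shape} does not match {frames.shape[0]} frames"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _read_frame(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        raise ValueError(f"{path.name}: grayscale images are not supported; RGB required")
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError(f"{path.name}: expected an RGB image, got shape {img.shape}")
    return img[..., :3]


def _read_timestamps(path: Path, names: list[str]) -> np.ndarray:
    """Two-column CSV (frame_name, time_h) -> times aligned with *names*."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("frame_name", "frame", "name"):
                continue
            table[row[0].strip()] = float(row[1])
    missing = [n for n in names if n not in table]
    if missing:
        raise ValueError(f"timestamps file {path} lacks entries for: {missing[:5]}")
    return np.array([table[n] for n in names], dtype=float)


def load_timelapse(
    directory: str | Path,
    pattern: str = "*.png",
    frame_interval_h: float | None = None,
    timestamps_file: str | Path | None = None,
) -> Timelapse:
    """Load a directory of frames into a :class:`Timelapse`.

    Files matching *pattern* are sorted lexicographically into time order
    (name them with zero-padded indices, e.g. ``img_00042.png``). Exactly
    one of *frame_interval_h* (uniform spacing, first frame at t=0) or
    *timestamps_file* (CSV of frame_name, time_h) must be given.
    """
    if (frame_interval_h is None) == (timestamps_file is None):
        raise ValueError(
            "exactly one of frame_interval_h or timestamps_file must be given"
        )
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"input directory does not exist: {directory}")
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(
            f"no frames found: no files match {pattern!r} in {directory}"
        )

    raw = [_read_frame(p) for p in paths]
    shapes = {a.shape for a in raw}
    if len(shapes) > 1:
        raise ValueError(f"frames have differing shapes: {sorted(shapes)}")

    dtype = raw[0].dtype
    bit_depth = 16 if dtype.itemsize > 1 else 8
    saturation = 2**bit_depth - 1
    frames = np.stack(raw).astype(float)

    for i, frame in enumerate(frames):
        if frame.max() >= saturation:
            warnings.warn(
                f"frame {paths[i].name}: saturated pixels at {saturation}",
                stacklevel=2,
            )

    if frame_interval_h is not None:
        if frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        times = frame_interval_h * np.arange(len(paths), dtype=float)
    else:
        times = _read_timestamps(Path(timestamps_file), [p.name for p in paths])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("timestamps are not strictly increasing in frame order")

    return Timelapse(frames=frames, times=times, bit_depth=bit_depth)


def subtract_background(
    stack: Timelapse,
    method: str = "first_frame_median",
    clip: bool = True,
) -> Timelapse:
    """Estimate and subtract a per-channel scalar background.

    ``first_frame_median`` (default) takes the per-channel median of frame
    0, robust because colonies are absent or tiny at the start of the
    timelapse. ``per_pixel_temporal_min`` takes the per-channel median of
    the per-pixel temporal minimum, tolerant of colonies already visible
    in frame 0 (requires T >= 2 to differ from the first method in any
    useful way) but biased low under camera noise, since the minimum of
    T noise draws sits below their mean.
    """
    if method == "first_frame_median":
        est = np.median(stack.frames[0], axis=(0, 1))
    elif method == "per_pixel_temporal_min":
        if stack.n_frames < 2:
            raise ValueError("per_pixel_temporal_min requires at least 2 frames")
        est = np.median(stack.frames.min(axis=0), axis=(0, 1))
    else:
        raise ValueError(f"unknown background method: {method!r}")

    frames = stack.frames - est[None, None, None, :]
    if clip:
        frames = np.clip(frames, 0.0, None)
    prev = np.asarray(stack.background, dtype=float)
    return replace(
        stack,
        frames=frames,
        background=tuple(float(v) for v in prev + est),
    )
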