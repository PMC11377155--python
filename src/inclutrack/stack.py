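"""Two-channel time-lapse container and TIFF round-trip.

A :class:`FrameStack` holds one ``(n_frames, height, width)`` intensity array
per named channel (GFP, RFP, optional LIPID / P62 / HOECHST) plus the
acquisition time of each frame in hours. On disk a stack is a directory with
one multi-page TIFF per channel (``{channel}.tif``) and a ``stack_meta.json``
sidecar recording channel names and acquisition times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

META_NAME = "stack_meta.json"


@dataclass
class FrameStack:
    """Named intensity channels sharing shape, frame count and time axis."""

    channels: Dict[str, np.ndarray]
    times_h: np.ndarray

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("FrameStack requires at least one channel")
        self.times_h = np.asarray(self.times_h, dtype=float)
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 3:
            raise ValidationError(f"channel arrays must be (n_frames, h, w), got {ref}")
        for name, shape in shapes.items():
            if shape != ref:
                raise ValidationError(
                    f"channel {name!r} shape {shape} does not match {ref}"
                )
        if self.times_h.shape != (ref[0],):
            raise ValidationError(
                f"times_h must have one entry per frame ({ref[0]}), got {self.times_h.shape}"
            )
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValidationError("acquisition times must be strictly increasing")
        for name, arr in self.channels.items():
            if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
                raise ValidationError(f"channel {name!r} has negative intensities")

    # ----------------------------------------------------------------- api

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> tuple:
        return tuple(self.channels)

    def frame(self, channel: str, index: int) -> np.ndarray:
        if channel not in self.channels:
            raise ValidationError(
                f"channel {channel!r} not in stack (has {sorted(self.channels)})"
            )
        if not 0 <= index < self.n_frames:
            raise ValidationError(
                f"frame index {index} out of range [0, {self.n_frames})"
            )
        return self.channels[channel][index]

    def equals(self, other: "FrameStack") -> bool:
        return (
            set(self.channels) == set(other.channels)
            and np.array_equal(self.times_h, other.times_h)
            and all(
                self.channels[c].dtype == other.channels[c].dtype
                and np.array_equal(self.channels[c], other.channels[c])
                for c in self.channels
            )
        )


def write_stack(stack: FrameStack, path) -> Path:
    """Write a stack as one multi-page TIFF per channel plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.channels.items():
        tifffile.imwrite(path / f"{name}.tif", arr, photometric="minisblack")
    meta = {
        "channels": list(stack.channels),
        "times_h": [float(t) for t in stack.times_h],
        "n_frames": stack.n_frames,
        "frame_shape": list(stack.frame_shape),
    }
    (path / META_NAME).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path, expected_channels: Sequence[str] | None = None) -> FrameStack:
    """Read a stack directory written by :func:`write_stack`.

    ``expected_channels``, when given, is validated against the sidecar; a
    mismatch (e.g. a single-channel directory read with a two-channel
    expectation) raises :class:`FormatError` naming the missing channel.
    """
    path = Path(path)
    meta_path = path / META_NAME
    if not meta_path.exists():
        raise FormatError(f"no {META_NAME} in {path}")
    meta = json.loads(meta_path.read_text())
    names = meta["channels"]
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in names]
        if missing:
            raise FormatError(f"stack at {path} is missing channel(s) {missing}")
    channels = {}
    for name in names:
        tif = path / f"{name}.tif"
        if not tif.exists():
            raise FormatError(f"missing channel file {tif} (channel {name!r})")
        arr = tifffile.imread(tif)
        if arr.ndim == 2:  # single frame round-trips as 2D
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"channel {name!r} in {path} is not a frame stack")
        channels[name] = arr
    shapes = {c: a.shape for c, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise FormatError(f"inconsistent channel shapes in {path}: {shapes}")
    try:
        return FrameStack(channels=channels, times_h=np.asarray(meta["times_h"]))
    except ValidationError as exc:
        raise FormatError(f"invalid stack at {path}: {exc}") from exc
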