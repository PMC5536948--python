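"""In-memory container for a multi-channel time-lapse movie."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import tifffile


@dataclass
class Movie:
    """A calibrated multi-channel movie.

    Attributes
    ----------
    channels : dict
        Maps channel role -> float32 array of shape (T, H, W).
    pixel_size : float
        µm per pixel.
    frame_interval : float
        Seconds between frames.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 0.162
    frame_interval: float = 30.0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel stacks have inconsistent shapes: {shapes}")

    @property
    def n_frames(self) -> int:
        if not self.channels:
            return 0
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1], arr.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"movie has no channel {role!r}; available: {list(self.channels)}")
        return self.channels[role]

    def frame_at(self, t: float) -> int:
        """Index of the frame nearest to time ``t`` (seconds)."""
        return int(np.clip(round(t / self.frame_interval), 0, self.n_frames - 1))

    # -- I/O ----------------------------------------------------------
    def save(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write one multi-page TIFF per channel; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for role, stack in self.channels.items():
            p = out_dir / f"{role}.tif"
            tifffile.imwrite(
                p,
                stack.astype(np.float32),
                photometric="minisblack",
                metadata={
                    "axes": "TYX",
                    "pixel_size_um": self.pixel_size,
                    "frame_interval_s": self.frame_interval,
                },
            )
            paths[role] = p
        return paths

    @classmethod
    def load(
        cls,
        channel_paths: dict[str, Union[str, Path]],
        pixel_size: float = 0.162,
        frame_interval: float = 30.0,
    ) -> "Movie":
        channels = {}
        for role, p in channel_paths.items():
            arr = tifffile.imread(p)
            if arr.ndim == 2:
                arr = arr[None]
            channels[role] = arr.astype(np.float32)
        return cls(channels=channels, pixel_size=pixel_size, frame_interval=frame_interval)
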