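"""The in-memory container for optical-mapping recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: recognised fluorescence channels
CHANNELS = ("voltage", "calcium")


@dataclass
class MovieStack:
    """A T x H x W fluorescence recording of a cardiac monolayer.

    Parameters
    ----------
    data:
        Intensity array, shape ``(T, H, W)``, arbitrary units. Frame index 0
        is the start of the recording; times are in milliseconds from there.
    frame_interval:
        Time between frames in ms (3.33 ms at 300 fps voltage, 5 ms at
        200 fps calcium).
    pixel_pitch:
        Physical size of one pixel in mm.
    channel:
        ``"voltage"`` or ``"calcium"``.
    meta:
        Free-form provenance dictionary. Processing steps append to
        ``meta["processing"]``.
    """

    data: np.ndarray
    frame_interval: float
    pixel_pitch: float
    channel: str = "voltage"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be T x H x W, got shape {self.data.shape}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Recording span in ms (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms from recording start."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, step: str | None = None, **step_params: Any) -> "MovieStack":
        """Return a copy holding ``data``, optionally recording a processing step."""
        meta = dict(self.meta)
        if step is not None:
            history = list(meta.get("processing", []))
            history.append({"step": step, **step_params})
            meta["processing"] = history
        return replace(self, data=data, meta=meta)
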