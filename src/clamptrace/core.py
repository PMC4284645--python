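"""Shared containers and errors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """Invalid scene or analysis configuration."""


class DataError(ValueError):
    """Input data violates a precondition."""


@dataclass
class ImageStack:
    """A multi-frame grayscale image stack with acquisition metadata.

    ``pixels`` is indexed ``(frame, row, col)`` in camera counts;
    coordinates are 0-based and intervals half-open.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    exposure_s: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise DataError(f"expected (frame, row, col) array, got shape {self.pixels.shape}")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame, s, frame 0 at t=0."""
        return np.arange(self.n_frames) * self.frame_interval_s
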