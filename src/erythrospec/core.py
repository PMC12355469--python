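"""Core containers shared across the pipeline.

A :class:`SpectralAxis` is an ordered wavenumber grid (cm^-1); an
:class:`HSImage` is a hyperspectral cube (y, x, channel) carrying its axis,
pixel size and free-form metadata.  Spectra themselves are plain 1-D
``numpy`` arrays aligned to an axis — the scipy convention, not a wrapper
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SpectralAxis", "HSImage"]


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("axis must be a 1-D array with at least 2 points")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def values(self) -> np.ndarray:
        return self.wavenumbers

    @property
    def step(self) -> float:
        """Median grid step (grids are uniform in practice)."""
        return float(np.median(np.diff(self.wavenumbers)))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting channels with lo <= wn <= hi."""
        if lo > hi:
            raise ValueError("window bounds reversed")
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def crop(self, intervals: list[tuple[float, float]]) -> "SpectralAxis":
        mask = np.zeros(len(self), dtype=bool)
        for lo, hi in intervals:
            mask |= self.window(lo, hi)
        if mask.sum() < 2:
            raise ValueError("crop leaves fewer than 2 channels")
        return SpectralAxis(self.wavenumbers[mask])

    @classmethod
    def raman_default(cls) -> "SpectralAxis":
        """600–3100 cm^-1 at 2 cm^-1 steps (spontaneous Raman mode)."""
        return cls(np.arange(600.0, 3100.0 + 1, 2.0))

    @classmethod
    def fingerprint(cls) -> "SpectralAxis":
        """600–1798 cm^-1 at 2 cm^-1 steps (600 channels)."""
        return cls(np.arange(600.0, 1800.0, 2.0))

    @classmethod
    def hssrs(cls, lo: float = 2800.0, hi: float = 3050.0,
              step: float = 6.0) -> "SpectralAxis":
        """Hyperspectral SRS grid: frames stepped 6 cm^-1 apart."""
        return cls(np.arange(lo, hi + step / 2, step))


@dataclass
class HSImage:
    """Hyperspectral cube, channel-last: ``data[y, x, channel]``."""

    data: np.ndarray
    axis: SpectralAxis
    pixel_size_um: float = 0.5
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be 3-D (y, x, channel)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"channel dimension {self.data.shape[2]} does not match "
                f"axis length {len(self.axis)}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def flatten(self) -> np.ndarray:
        """Pixels-by-channels view used by matrix factorisations."""
        return self.data.reshape(-1, self.data.shape[2])

    def frame_at(self, wavenumber: float) -> np.ndarray:
        """Single-channel image at the grid point nearest ``wavenumber``."""
        return self.data[:, :, self.axis.index_of(wavenumber)]

    def total_intensity(self) -> np.ndarray:
        return self.data.sum(axis=2)
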