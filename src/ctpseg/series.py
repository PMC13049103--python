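"""Core in-memory container for 4D CT perfusion data.

A :class:`PerfusionSeries` holds the dynamic acquisition as a
``(frames, slices, rows, cols)`` array of Hounsfield units together with the
voxel spacing in mm and the acquisition time of every frame in seconds.
Frame/slice/row/col indices are 0-based and physical times are measured from
the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["PerfusionSeries"]


@dataclass
class PerfusionSeries:
    """4D HU grid with spacing and per-frame acquisition times.

    Parameters
    ----------
    data:
        Array of shape ``(n_frames, slices, rows, cols)`` in HU.
    spacing:
        Voxel spacing ``(dz, dy, dx)`` in mm, all positive.
    frame_times:
        Strictly increasing acquisition times in seconds, one per frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ConfigError(
                f"series data must be 4D (frames, slices, rows, cols); got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be 3 positive values (dz, dy, dx); got {self.spacing}")
        if self.frame_times is None:
            self.frame_times = np.arange(self.data.shape[0], dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.data.shape[0],):
            raise ConfigError(
                f"frame_times length {self.frame_times.size} does not match "
                f"frame count {self.data.shape[0]}"
            )
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ConfigError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(slices, rows, cols)``."""
        return self.data.shape[1:]

    @property
    def frame_interval(self) -> float:
        """Median inter-frame spacing in seconds (uniform for raw acquisitions)."""
        if self.n_frames < 2:
            raise ConfigError("frame interval undefined for a single-frame series")
        return float(np.median(np.diff(self.frame_times)))

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0
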