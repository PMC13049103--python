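"""Grid harmonization: thick-slice synthesis and resampling to a reference grid.

Multi-modality stroke CT studies mix voxel grids — perfusion series with
thick slices, angiography with thin ones. Two operations bring everything
onto a common reference: averaging groups of thin slices into synthetic
thick slices, and interpolating a volume onto an arbitrary target grid in
physical coordinates (trilinear for intensities, nearest-neighbour for label
masks so binarity and nesting survive). Inputs are assumed co-registered;
a hook accepts an externally produced rigid transform for data that is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError

__all__ = ["GridSpec", "synthesize_thick_slices", "resample_to_grid"]


@dataclass(frozen=True)
class GridSpec:
    """A voxel grid in physical space: shape, spacing (mm) and origin (mm).

    Axis order is (slices, rows, cols) = (z, y, x); voxel centers sit at
    ``origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ConfigError(f"grid shape must be 3 values >= 1; got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError(f"grid spacing must be 3 positive values; got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical range covered by voxel centers, per axis."""
        return tuple(
            (o, o + (n - 1) * s) for o, s, n in zip(self.origin, self.spacing, self.shape)
        )

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing), "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d.get("origin", (0, 0, 0))))


def synthesize_thick_slices(
    volume: np.ndarray, spacing: tuple[float, float, float], factor: int
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Average consecutive non-overlapping groups of ``factor`` thin slices.

    The output z-spacing is the input z-spacing times ``factor``; the
    in-plane grid is unchanged. Trailing slices that do not fill a complete
    group are dropped.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ConfigError(f"expected a 3D volume; got {volume.ndim}D")
    if factor < 1:
        raise ConfigError(f"factor must be >= 1; got {factor}")
    n_slices = volume.shape[0]
    if factor > n_slices:
        raise ConfigError(f"factor {factor} exceeds slice count {n_slices}")
    n_groups = n_slices // factor
    grouped = volume[: n_groups * factor].reshape((n_groups, factor) + volume.shape[1:])
    thick = grouped.mean(axis=1)
    new_spacing = (spacing[0] * factor, spacing[1], spacing[2])
    return thick, new_spacing


def _grids_overlap(source: GridSpec, target: GridSpec) -> bool:
    for (slo, shi), (tlo, thi) in zip(source.extent, target.extent):
        if thi < slo or tlo > shi:
            return False
    return True


def resample_to_grid(
    volume: np.ndarray,
    source: GridSpec,
    target: GridSpec,
    order: str = "linear",
    background: float = 0.0,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Interpolate ``volume`` from its source grid onto a target grid.

    ``order`` is ``"linear"`` (trilinear, for intensities) or ``"nearest"``
    (for label masks). Target voxels outside the source extent receive
    ``background``. ``transform`` optionally applies an externally produced
    rigid transform ``(R, t)`` mapping target physical coordinates into
    source physical coordinates (``x_src = R @ x_tgt + t``) before sampling;
    by default grids are assumed co-registered.
    """
    volume = np.asarray(volume)
    if volume.shape != source.shape:
        raise ConfigError(f"volume shape {volume.shape} does not match source grid {source.shape}")
    if order not in ("linear", "nearest"):
        raise ConfigError(f"order must be 'linear' or 'nearest'; got {order!r}")
    if transform is None and not _grids_overlap(source, target):
        raise ConfigError(
            f"source grid extent {GridSpec.extent.fget(source)} and target grid extent "
            f"{GridSpec.extent.fget(target)} do not overlap"
        )
    was_bool = volume.dtype == bool
    idx = np.indices(target.shape, dtype=float)
    phys = [
        idx[k] * target.spacing[k] + target.origin[k] for k in range(3)
    ]
    if transform is not None:
        r, t = np.asarray(transform[0], dtype=float), np.asarray(transform[1], dtype=float)
        stacked = np.stack(phys)
        phys = [
            r[k, 0] * stacked[0] + r[k, 1] * stacked[1] + r[k, 2] * stacked[2] + t[k]
            for k in range(3)
        ]
    coords = np.stack(
        [(phys[k] - source.origin[k]) / source.spacing[k] for k in range(3)]
    )
    out = ndimage.map_coordinates(
        volume.astype(np.float64),
        coords,
        order=1 if order == "linear" else 0,
        mode="constant",
        cval=float(background),
    )
    return out > 0.5 if was_bool else out
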