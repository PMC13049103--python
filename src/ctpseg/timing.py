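"""Temporal sampling of 4D CT perfusion series.

A multiphase-CTA (mCTA) acquisition consists of a bolus-triggered arterial
phase followed by late arterial and venous phases 13 s and 21 s later. A CT
perfusion (CTP) series, acquired every 1.5 s over ~40-66 s, contains these
phases implicitly. This module extracts time-attenuation curves (TACs) from
arterial/venous reference ROIs and turns them into *timing plans*: named
strategies that pick a small set of reference frames from the series and
average each with its two neighbours into one phase image.

Strategies
----------
fixed_mcta
    Initial phase two frames before the arterial peak, later phases at
    +13 s and +21 s — the mCTA protocol transplanted onto the CTP series.
varying_mcta
    Like fixed_mcta, but the initial reference is ``t_Amax + delta`` with a
    random integer offset delta drawn uniformly from {-5, ..., +2} frames,
    emulating the bolus-arrival variability of a real triggered mCTA.
peak / peak_baseline
    Phases at the arterial peak, the venous peak, and a late point obtained
    by extrapolating the arterial-to-venous gap; ``peak_baseline`` prepends
    a native (pre-contrast) phase referenced at the third frame.
equidistant
    Eight non-overlapping windows of three consecutive frames covering the
    first 24 frames.

Every non-equidistant phase is the mean of exactly three consecutive frames
centred on its reference. If the last window would run past the series, its
reference is clamped to the second-last frame; an analogous rule keeps early
windows inside the series at the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, TimingError
from .series import PerfusionSeries

__all__ = [
    "TAC",
    "TimingPlan",
    "PhaseStack",
    "extract_tac",
    "find_peak",
    "seconds_to_frames",
    "plan_fixed_mcta",
    "plan_varying_mcta",
    "plan_peak",
    "plan_equidistant",
    "apply_plan",
    "MCTA_PHASE_DELAYS_S",
]

#: Late-phase delays of the mCTA protocol, seconds after the initial phase.
MCTA_PHASE_DELAYS_S: tuple[float, float] = (13.0, 21.0)

#: Discrete uniform support of the varying-mCTA start offset, in frames.
VARYING_MCTA_DELTA_RANGE: tuple[int, int] = (-5, 2)


@dataclass
class TAC:
    """Time-attenuation curve: mean ROI attenuation (HU) per frame."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ConfigError("TAC times and values must be equal-length 1D arrays")
        if self.times.size == 0:
            raise ConfigError("TAC must contain at least one sample")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigError("TAC times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TimingPlan:
    """A named strategy resolved to reference frames and averaging windows."""

    strategy: str
    reference_indices: tuple[int, ...]
    windows: tuple[tuple[int, ...], ...]
    t_amax: int | None = None
    delta: int | None = None
    clamped: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.clamped:
            self.clamped = tuple(False for _ in self.reference_indices)
        if len(self.windows) != len(self.reference_indices):
            raise ConfigError("one window per reference index required")
        if any(list(w) != sorted(w) or w[-1] - w[0] != len(w) - 1 for w in self.windows):
            raise ConfigError("windows must be contiguous frame runs")
        if list(self.reference_indices) != sorted(self.reference_indices):
            raise ConfigError("reference indices must be non-decreasing")

    @property
    def n_phases(self) -> int:
        return len(self.reference_indices)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "reference_indices": list(self.reference_indices),
            "windows": [list(w) for w in self.windows],
            "t_amax": self.t_amax,
            "delta": self.delta,
            "clamped": list(self.clamped),
        }


@dataclass
class PhaseStack:
    """Multi-channel 3D stack produced by applying a timing plan."""

    data: np.ndarray  # (channels, slices, rows, cols)
    spacing: tuple[float, float, float]
    reference_times: np.ndarray
    plan: TimingPlan


def extract_tac(series: PerfusionSeries, roi: np.ndarray) -> TAC:
    """Mean HU over the ROI voxels for every frame."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.grid_shape:
        raise ConfigError(
            f"ROI shape {roi.shape} does not match series grid {series.grid_shape}"
        )
    if not roi.any():
        raise ConfigError("ROI is empty")
    values = series.data[:, roi].mean(axis=1)
    return TAC(times=series.frame_times.copy(), values=values)


def find_peak(tac: TAC) -> int:
    """Frame index of the maximum TAC value; earliest index on ties."""
    return int(np.argmax(tac.values))


def seconds_to_frames(dt: float, interval: float) -> int:
    """Convert a time offset to a frame offset, rounding half up."""
    if interval <= 0:
        raise ConfigError(f"frame interval must be positive; got {interval}")
    return int(math.floor(dt / interval + 0.5))


def _window(ref: int) -> tuple[int, int, int]:
    return (ref - 1, ref, ref + 1)


def _clamp_refs(refs: list[int], n_frames: int) -> tuple[list[int], list[bool]]:
    """Keep each 3-frame window inside [0, n_frames); flag adjusted phases.

    A reference whose window would run past the last frame is reset to the
    second-last frame (window = last three frames); one whose window would
    start before frame 0 is raised to frame 1.
    """
    clamped = [False] * len(refs)
    out = []
    for i, r in enumerate(refs):
        if r + 1 > n_frames - 1:
            r = n_frames - 2
            clamped[i] = True
        if r - 1 < 0:
            r = 1
            clamped[i] = True
        out.append(r)
    return out, clamped


def _mcta_like_plan(
    strategy: str,
    t0: int,
    t_amax: int,
    interval: float,
    n_frames: int,
    delta: int | None = None,
) -> TimingPlan:
    if n_frames < 5:
        raise ConfigError(f"need at least 5 frames for an mCTA-like plan; got {n_frames}")
    offsets = [seconds_to_frames(d, interval) for d in MCTA_PHASE_DELAYS_S]
    refs = [t0, t0 + offsets[0], t0 + offsets[1]]
    refs, clamped = _clamp_refs(refs, n_frames)
    return TimingPlan(
        strategy=strategy,
        reference_indices=tuple(refs),
        windows=tuple(_window(r) for r in refs),
        t_amax=t_amax,
        delta=delta,
        clamped=tuple(clamped),
    )


def plan_fixed_mcta(aif: TAC, interval: float, n_frames: int) -> TimingPlan:
    """mCTA protocol timing anchored two frames before the arterial peak."""
    t_amax = find_peak(aif)
    return _mcta_like_plan("fixed_mcta", t_amax - 2, t_amax, interval, n_frames)


def plan_varying_mcta(aif: TAC, interval: float, n_frames: int, rng_seed: int) -> TimingPlan:
    """mCTA-like timing with a random start offset around the arterial peak."""
    rng = np.random.default_rng(rng_seed)
    lo, hi = VARYING_MCTA_DELTA_RANGE
    delta = int(rng.integers(lo, hi + 1))
    t_amax = find_peak(aif)
    return _mcta_like_plan(
        "varying_mcta", t_amax + delta, t_amax, interval, n_frames, delta=delta
    )


def plan_peak(
    aif: TAC,
    venous: TAC,
    include_baseline: bool = False,
    n_frames: int | None = None,
) -> TimingPlan:
    """Arterial-peak / venous-peak / extrapolated-late timing.

    The third reference extends the arterial-to-venous gap past the venous
    peak. With ``include_baseline`` a native pre-contrast phase referenced at
    the third frame (index 2) is prepended.
    """
    if not np.array_equal(aif.times, venous.times):
        raise ConfigError("arterial and venous TACs must share the same time axis")
    if n_frames is None:
        n_frames = len(aif)
    t_amax = find_peak(aif)
    t_vmax = find_peak(venous)
    if t_vmax <= t_amax:
        raise TimingError(
            f"venous peak (frame {t_vmax}) must come after arterial peak (frame {t_amax}); "
            "check the reference-vessel ROI"
        )
    refs = [t_amax, t_vmax, t_vmax + (t_vmax - t_amax)]
    if include_baseline:
        refs = [2] + refs
    refs, clamped = _clamp_refs(refs, n_frames)
    return TimingPlan(
        strategy="peak_baseline" if include_baseline else "peak",
        reference_indices=tuple(refs),
        windows=tuple(_window(r) for r in refs),
        t_amax=t_amax,
        clamped=tuple(clamped),
    )


def plan_equidistant(n_frames: int) -> TimingPlan:
    """Eight non-overlapping 3-frame windows covering frames 0-23."""
    if n_frames < 24:
        raise ConfigError(
            f"equidistant timing needs the 25-frame minimum series (24 usable frames "
            f"for 8 windows of 3); got {n_frames}"
        )
    windows = tuple(tuple(range(3 * i, 3 * i + 3)) for i in range(8))
    refs = tuple(3 * i + 1 for i in range(8))
    return TimingPlan(strategy="equidistant", reference_indices=refs, windows=windows)


def apply_plan(series: PerfusionSeries, plan: TimingPlan) -> PhaseStack:
    """Average each plan window voxelwise into one phase channel."""
    n = series.n_frames
    for w in plan.windows:
        if w[0] < 0 or w[-1] >= n:
            raise ConfigError(
                f"window {w} is outside the series (0..{n - 1}); plan was not clamped"
            )
    channels = np.stack([series.data[list(w)].mean(axis=0) for w in plan.windows])
    return PhaseStack(
        data=channels,
        spacing=series.spacing,
        reference_times=series.frame_times[list(plan.reference_indices)].copy(),
        plan=plan,
    )
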