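"""Uncertainty-aware stroke lesion labels and a threshold stand-in segmenter.

The ground truth of a stroke segmentation study carries irreducible
annotation uncertainty: raters cannot place a single sharp lesion boundary,
so each class (infarct core, hypoperfused volume = core + penumbra) is
delineated twice, with a nested *inner* contour bounding the minimum
plausible extent and an *outer* contour bounding the maximum. The band
between the two encodes the uncertain region. Prior (chronic) infarcts are a
separate flat class, mutually exclusive with the acute lesion.

This module provides:

* :class:`UncertainLabel` — the nested-mask container with validation;
* :func:`to_region_masks` — the hierarchical region encoding in which a
  voxel inside the inner contour is positive for both the inner- and
  outer-region channels while a voxel in the annular "tube" is positive only
  for the outer channel;
* :func:`proxy_maps` — simple per-voxel hemodynamic summary maps (area under
  the baseline-subtracted enhancement curve, time to peak, maximum slope).
  These are deliberately *not* deconvolution-based CBV/CBF/TMAX maps; they
  are plain descriptive statistics of the time-attenuation curve that carry
  the same qualitative contrast (less enhancement and later arrival inside
  the lesion);
* :func:`standin_segment` — a pluggable threshold-based segmenter producing
  inner/outer predictions from the proxy maps. It plays the role of the
  learned segmentation model in the pipeline; externally produced
  predictions in the same inner/outer mask format can be dropped in
  unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, LabelValidationError
from .series import PerfusionSeries

__all__ = [
    "UncertainLabel",
    "RegionMasks",
    "ProxyMaps",
    "SegmenterThresholds",
    "to_region_masks",
    "validate_label",
    "proxy_maps",
    "standin_segment",
]


@dataclass
class UncertainLabel:
    """Nested inner/outer masks per class plus a flat prior-infarct mask."""

    core_inner: np.ndarray
    core_outer: np.ndarray
    hypo_inner: np.ndarray
    hypo_outer: np.ndarray
    prior_infarct: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("core_inner", "core_outer", "hypo_inner", "hypo_outer", "prior_infarct"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.spacing = tuple(float(s) for s in self.spacing)
        shapes = {m.shape for m in self.masks().values()}
        if len(shapes) != 1:
            raise LabelValidationError(f"label channels have mismatched shapes: {shapes}")

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "core_inner": self.core_inner,
            "core_outer": self.core_outer,
            "hypo_inner": self.hypo_inner,
            "hypo_outer": self.hypo_outer,
            "prior_infarct": self.prior_infarct,
        }

    def class_pair(self, cls: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (inner, outer) masks for ``cls`` in {'core', 'hypo'}."""
        if cls == "core":
            return self.core_inner, self.core_outer
        if cls == "hypo":
            return self.hypo_inner, self.hypo_outer
        raise ConfigError(f"unknown label class {cls!r}; expected 'core' or 'hypo'")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @classmethod
    def empty(cls, shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> "UncertainLabel":
        z = np.zeros(shape, dtype=bool)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), spacing)


@dataclass
class RegionMasks:
    """Hierarchical region channels derived from an :class:`UncertainLabel`.

    The inner-region channel of a class is positive wherever the inner
    contour is, the outer-region channel wherever the outer contour is, so a
    voxel inside the inner contour is positive in both and a tube voxel only
    in the outer one. The prior-infarct channel passes through flat.
    """

    core_inner_region: np.ndarray
    core_outer_region: np.ndarray
    hypo_inner_region: np.ndarray
    hypo_outer_region: np.ndarray
    prior_infarct: np.ndarray

    def to_label(self, spacing: tuple[float, float, float]) -> UncertainLabel:
        """Invert the region encoding back to an :class:`UncertainLabel`."""
        return UncertainLabel(
            self.core_inner_region,
            self.core_outer_region,
            self.hypo_inner_region,
            self.hypo_outer_region,
            self.prior_infarct,
            spacing,
        )


@dataclass
class ValidationReport:
    passed: bool
    violations: dict[str, int]
    empty_classes: tuple[str, ...]
    messages: tuple[str, ...] = ()


def validate_label(label: UncertainLabel) -> ValidationReport:
    """Check the nesting and mutual-exclusion invariants of a label.

    Reports per-invariant offending voxel counts; never raises.
    """
    violations = {
        "core_inner_outside_core_outer": int(np.sum(label.core_inner & ~label.core_outer)),
        "hypo_inner_outside_hypo_outer": int(np.sum(label.hypo_inner & ~label.hypo_outer)),
        "core_outer_outside_hypo_outer": int(np.sum(label.core_outer & ~label.hypo_outer)),
        "prior_infarct_overlaps_hypo_outer": int(np.sum(label.prior_infarct & label.hypo_outer)),
    }
    empty = tuple(name for name, m in label.masks().items() if not m.any())
    messages = tuple(f"{k}: {v} voxels" for k, v in violations.items() if v > 0)
    return ValidationReport(
        passed=not any(violations.values()),
        violations=violations,
        empty_classes=empty,
        messages=messages,
    )


def to_region_masks(label: UncertainLabel) -> RegionMasks:
    """Derive hierarchical region channels, enforcing label validity first."""
    report = validate_label(label)
    if not report.passed:
        raise LabelValidationError(
            "label violates nesting/exclusion invariants: " + "; ".join(report.messages)
        )
    return RegionMasks(
        core_inner_region=label.core_inner.copy(),
        core_outer_region=label.core_outer.copy(),
        hypo_inner_region=label.hypo_inner.copy(),
        hypo_outer_region=label.hypo_outer.copy(),
        prior_infarct=label.prior_infarct.copy(),
    )


@dataclass
class ProxyMaps:
    """Per-voxel hemodynamic summary maps.

    auc : HU*s, trapezoidal integral of the positive part of the
        baseline-subtracted time course.
    ttp : seconds, acquisition time of the per-voxel maximum.
    max_slope : HU/s, maximum forward difference divided by the frame gap.
    """

    auc: np.ndarray
    ttp: np.ndarray
    max_slope: np.ndarray
    frame_times: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def proxy_maps(series: PerfusionSeries, baseline_frames: int = 1) -> ProxyMaps:
    """Compute AUC / time-to-peak / max-slope maps from a perfusion series.

    ``baseline_frames`` leading frames define the pre-contrast baseline.
    """
    n = series.n_frames
    if n < 2:
        raise ConfigError("proxy maps need at least 2 frames; got a degenerate series")
    if not 1 <= baseline_frames < n:
        raise ConfigError(
            f"baseline_frames must be in [1, {n - 1}]; got {baseline_frames}"
        )
    data = series.data.astype(np.float64)
    times = series.frame_times
    baseline = data[:baseline_frames].mean(axis=0)
    signal = np.clip(data - baseline, 0.0, None)
    auc = np.trapezoid(signal, x=times, axis=0)
    ttp = times[np.argmax(data, axis=0)]
    dt = np.diff(times).reshape(-1, 1, 1, 1)
    max_slope = (np.diff(data, axis=0) / dt).max(axis=0)
    return ProxyMaps(auc=auc, ttp=ttp, max_slope=max_slope, frame_times=times.copy())


@dataclass
class SegmenterThresholds:
    """Config of the threshold stand-in segmenter.

    Delay thresholds are in seconds of time-to-peak delay relative to the
    normal-tissue reference; deficit thresholds are fractional AUC reductions
    relative to the normal-tissue reference AUC. Strict (inner-contour)
    thresholds must be at least as restrictive as lenient (outer) ones.
    """

    ttp_delay_lenient: float = 1.0
    ttp_delay_strict: float = 2.5
    hypo_deficit_lenient: float = 0.15
    hypo_deficit_strict: float = 0.22
    core_deficit_lenient: float = 0.42
    core_deficit_strict: float = 0.50
    min_enhancement_fraction: float = 0.1
    closing_radius_voxels: int = 1
    min_component_ml: float = 0.1

    def __post_init__(self) -> None:
        for lenient, strict in (
            (self.ttp_delay_lenient, self.ttp_delay_strict),
            (self.hypo_deficit_lenient, self.hypo_deficit_strict),
            (self.core_deficit_lenient, self.core_deficit_strict),
        ):
            if strict < lenient:
                raise ConfigError(
                    f"strict threshold {strict} is more lenient than lenient threshold {lenient}"
                )
        if self.closing_radius_voxels < 0 or self.min_component_ml < 0:
            raise ConfigError("post-processing parameters must be non-negative")


def _postprocess(mask: np.ndarray, thresholds: SegmenterThresholds, voxel_volume_ml: float) -> np.ndarray:
    """Morphological closing + small-component removal (compactness surrogate)."""
    if not mask.any():
        return mask
    structure = ndimage.generate_binary_structure(3, 1)
    if thresholds.closing_radius_voxels > 0:
        mask = ndimage.binary_closing(
            mask, structure=structure, iterations=thresholds.closing_radius_voxels
        )
    min_voxels = int(np.ceil(thresholds.min_component_ml / voxel_volume_ml))
    if min_voxels > 1:
        labelled, n = ndimage.label(mask, structure=structure)
        if n:
            sizes = np.bincount(labelled.ravel())
            keep = sizes >= min_voxels
            keep[0] = False
            mask = keep[labelled]
    return mask


def standin_segment(
    maps: ProxyMaps,
    thresholds: SegmenterThresholds,
    spacing: tuple[float, float, float],
    normal_mask: np.ndarray | None = None,
) -> UncertainLabel:
    """Threshold-based stand-in segmenter producing nested inner/outer masks.

    Reference normal-tissue statistics (median AUC and median time-to-peak)
    are taken over ``normal_mask`` when given, otherwise over the whole
    volume (valid when the lesion occupies a minority of voxels). A voxel is
    hypoperfused when its arrival is delayed beyond the delay threshold
    (counted only where a bolus actually passes, i.e. where the AUC exceeds
    ``min_enhancement_fraction`` of the reference) or when its enhancement
    deficit exceeds the hypoperfusion deficit threshold. Core additionally
    requires a deep enhancement deficit. Strict thresholds produce the inner
    contour, lenient ones the outer, so nesting holds by construction; a
    final intersection pass re-imposes it after morphology.

    The prediction's prior-infarct channel is always empty: the stand-in has
    no signal model for chronic infarcts.
    """
    ref = normal_mask if normal_mask is not None else np.ones(maps.auc.shape, dtype=bool)
    if not ref.any():
        raise ConfigError("normal_mask must contain at least one voxel")
    auc_ref = float(np.median(maps.auc[ref]))
    if auc_ref <= 0:
        # no contrast passage anywhere: nothing to segment
        return UncertainLabel.empty(maps.auc.shape, spacing)
    enhanced = maps.auc > thresholds.min_enhancement_fraction * auc_ref
    ttp_ref = float(np.median(maps.ttp[ref & enhanced])) if (ref & enhanced).any() else 0.0

    deficit = 1.0 - maps.auc / auc_ref
    delay = maps.ttp - ttp_ref

    hypo_outer = (enhanced & (delay > thresholds.ttp_delay_lenient)) | (
        deficit > thresholds.hypo_deficit_lenient
    )
    hypo_inner = (enhanced & (delay > thresholds.ttp_delay_strict)) | (
        deficit > thresholds.hypo_deficit_strict
    )
    core_outer = hypo_outer & (deficit > thresholds.core_deficit_lenient)
    core_inner = hypo_inner & (deficit > thresholds.core_deficit_strict)

    voxel_volume_ml = float(np.prod(spacing)) / 1000.0
    hypo_outer = _postprocess(hypo_outer, thresholds, voxel_volume_ml)
    hypo_inner = _postprocess(hypo_inner, thresholds, voxel_volume_ml) & hypo_outer
    core_outer = _postprocess(core_outer, thresholds, voxel_volume_ml) & hypo_outer
    core_inner = _postprocess(core_inner, thresholds, voxel_volume_ml) & core_outer & hypo_inner

    return UncertainLabel(
        core_inner=core_inner,
        core_outer=core_outer,
        hypo_inner=hypo_inner,
        hypo_outer=hypo_outer,
        prior_infarct=np.zeros(maps.auc.shape, dtype=bool),
        spacing=spacing,
    )
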