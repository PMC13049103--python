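"""Seeded synthetic 4D CT perfusion phantom with nested ground truth.

The phantom emulates, at desk scale, the raw material of a multi-modality
acute-stroke CT study: a dynamic perfusion series (default 44 frames at
1.5-s intervals, 66 s of coverage), arterial and venous reference-vessel
ROIs, a lesion with reduced and delayed tissue enhancement, nested
inner/outer ground-truth contours for infarct core and hypoperfused volume,
and derived static scans (NCCT, single-phase CTA, three-phase mCTA).

Enhancement curves follow the gamma-variate bolus model

    g(t) = A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)

for t > t0 and 0 otherwise, normalised so the maximum equals the amplitude
``A`` and peaking at ``t0 + alpha*beta``. Tissue receives a delayed,
dispersed, strongly attenuated copy of the arterial curve; the venous
reference a delayed, broadened copy at full amplitude.

The ground-truth band encodes annotation uncertainty: the four nested
ellipsoids bound the minimum and maximum plausible extents of core and
hypoperfused volume, while the *physiological* lesion — the region whose
time courses are actually altered — is the mid-surface of each band. A
perfect segmenter therefore lands inside the band, exactly the situation the
uncertainty-aware evaluation is designed for.

No skull, beam hardening, or patient motion is simulated: the phantom tests
the computation downstream of registration, not robustness to artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _nifti
from .errors import ConfigError, FormatError, GeometryError
from .labels import UncertainLabel
from .series import PerfusionSeries
from .timing import MCTA_PHASE_DELAYS_S, seconds_to_frames

__all__ = [
    "AifParams",
    "LesionGeometry",
    "LesionHemodynamics",
    "Ellipsoid",
    "PhantomConfig",
    "PhantomCase",
    "gamma_variate",
    "make_phantom",
    "derive_static_scans",
    "write_case",
    "read_case",
    "contralateral_mask",
    "TISSUE_BASELINE_HU",
    "BLOOD_BASELINE_HU",
]

#: Unenhanced brain parenchyma attenuation.
TISSUE_BASELINE_HU = 35.0
#: Unenhanced blood-pool attenuation (vessel ROIs).
BLOOD_BASELINE_HU = 45.0


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate parameters of the arterial input function."""

    t0: float = 8.0  # bolus arrival, s
    alpha: float = 3.0  # shape (dimensionless)
    beta: float = 1.8  # scale, s
    amplitude: float = 300.0  # peak enhancement above baseline, HU


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm, (z, y, x) order."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(s * factor for s in self.semi_axes))


@dataclass(frozen=True)
class LesionGeometry:
    """Four nested ellipsoids sharing one center: the annotation bands.

    inner core <= outer core <= inner hypoperfusion <= outer hypoperfusion,
    strict in every semi-axis.
    """

    center: tuple[float, float, float] = (16.0, 32.0, 20.0)
    core_inner: tuple[float, float, float] = (5.0, 8.0, 8.0)
    core_outer: tuple[float, float, float] = (7.0, 10.0, 10.0)
    hypo_inner: tuple[float, float, float] = (9.0, 13.0, 12.0)
    hypo_outer: tuple[float, float, float] = (11.0, 16.0, 14.0)

    def nested_semi_axes(self) -> tuple[tuple[float, float, float], ...]:
        return (self.core_inner, self.core_outer, self.hypo_inner, self.hypo_outer)

    def ellipsoid(self, which: str) -> Ellipsoid:
        return Ellipsoid(self.center, getattr(self, which))

    def mid_core(self) -> Ellipsoid:
        """Mid-surface of the core annotation band: the physiological core."""
        semi = tuple((a + b) / 2.0 for a, b in zip(self.core_inner, self.core_outer))
        return Ellipsoid(self.center, semi)

    def mid_hypo(self) -> Ellipsoid:
        semi = tuple((a + b) / 2.0 for a, b in zip(self.hypo_inner, self.hypo_outer))
        return Ellipsoid(self.center, semi)


@dataclass(frozen=True)
class LesionHemodynamics:
    """Enhancement alteration inside the physiological lesion.

    Amplitude reductions are fractions of the normal tissue amplitude that
    are *lost* (core loses at least as much as penumbra); delays are added
    to the tissue bolus arrival, in seconds.
    """

    amplitude_reduction_core: float = 0.6
    amplitude_reduction_penumbra: float = 0.3
    delay_core: float = 4.0
    delay_penumbra: float = 2.0


@dataclass
class PhantomConfig:
    """Full specification of one synthetic case. All lengths in mm, times in s."""

    grid_shape: tuple[int, int, int] = (16, 64, 64)  # (slices, rows, cols)
    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (dz, dy, dx)
    n_frames: int = 44
    frame_interval: float = 1.5
    aif_params: AifParams = field(default_factory=AifParams)
    venous_delay: float = 3.5
    venous_broadening: float = 1.5
    tissue_gain: float = 0.12  # tissue amplitude as fraction of AIF amplitude
    tissue_delay: float = 2.0  # bolus arrival delay in normal tissue, s
    tissue_broadening: float = 2.5  # dispersion of the tissue curve (scales beta)
    lesion_geometry: LesionGeometry = field(default_factory=LesionGeometry)
    lesion_hemodynamics: LesionHemodynamics = field(default_factory=LesionHemodynamics)
    prior_infarct: Ellipsoid | None = None
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 25:
            raise ConfigError(f"n_frames must be >= 25; got {self.n_frames}")
        if self.frame_interval <= 0:
            raise ConfigError(f"frame_interval must be positive; got {self.frame_interval}")
        if self.aif_params.alpha <= 0 or self.aif_params.beta <= 0:
            raise ConfigError("gamma-variate alpha and beta must be positive")
        if self.venous_delay <= 0 or self.venous_broadening <= 1:
            raise ConfigError("venous_delay must be > 0 and venous_broadening > 1")
        if not 0 < self.tissue_gain <= 1:
            raise ConfigError(f"tissue_gain must be in (0, 1]; got {self.tissue_gain}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative; got {self.noise_sd}")
        hd = self.lesion_hemodynamics
        for r in (hd.amplitude_reduction_core, hd.amplitude_reduction_penumbra):
            if not 0 <= r <= 1:
                raise ConfigError(f"amplitude reductions must be in [0, 1]; got {r}")
        if hd.amplitude_reduction_core < hd.amplitude_reduction_penumbra:
            raise ConfigError(
                "core amplitude reduction must be at least the penumbra reduction"
            )
        shells = self.lesion_geometry.nested_semi_axes()
        for inner, outer in zip(shells, shells[1:]):
            if not all(i < o for i, o in zip(inner, outer)):
                raise ConfigError(
                    f"lesion semi-axes must be strictly nested; {inner} vs {outer}"
                )
        extent = tuple(
            (n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing)
        )
        ellipsoids = [self.lesion_geometry.ellipsoid("hypo_outer")]
        if self.prior_infarct is not None:
            ellipsoids.append(self.prior_infarct)
        for ell in ellipsoids:
            for c, a, e in zip(ell.center, ell.semi_axes, extent):
                if c - a < 0 or c + a > e:
                    raise GeometryError(
                        f"ellipsoid (center {ell.center}, semi-axes {ell.semi_axes}) "
                        f"does not fit inside the grid extent {extent} mm"
                    )

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PhantomCase:
    """A generated case: the 4D series, ground truth, ROIs and static scans."""

    series: PerfusionSeries
    gt: UncertainLabel
    aif_roi: np.ndarray
    venous_roi: np.ndarray
    ncct: np.ndarray
    cta: np.ndarray
    mcta: np.ndarray  # (3, slices, rows, cols)
    config: PhantomConfig
    arterial_peak_index: int
    mcta_frame_indices: tuple[int, int, int]


def gamma_variate(
    t: np.ndarray | float, t0: float, alpha: float, beta: float, amplitude: float
) -> np.ndarray | float:
    """Normalised gamma-variate bolus curve.

    Zero for ``t <= t0``; rises as ``(t - t0)**alpha``, decays with scale
    ``beta`` and is scaled so the maximum (at ``t0 + alpha*beta``) equals
    ``amplitude``.
    """
    if alpha <= 0 or beta <= 0:
        raise ConfigError(f"alpha and beta must be positive; got alpha={alpha}, beta={beta}")
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = amplitude * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta)
    y = np.where(dt > 0, y, 0.0)
    return y if y.ndim else float(y)


def _voxel_coords(
    grid_shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_ellipsoid(
    ell: Ellipsoid,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Voxel-center-inside test for an axis-aligned ellipsoid."""
    zz, yy, xx = _voxel_coords(grid_shape, spacing)
    cz, cy, cx = ell.center
    az, ay, ax = ell.semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def contralateral_mask(mask: np.ndarray) -> np.ndarray:
    """Mirror a mask across the mid-sagittal plane (the column axis)."""
    return mask[:, :, ::-1]


def _sphere_roi(
    center_mm: tuple[float, float, float],
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    return rasterize_ellipsoid(
        Ellipsoid(center_mm, (radius_mm,) * 3), grid_shape, spacing
    )


def make_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one deterministic case from a validated config."""
    config.validate()
    shape = config.grid_shape
    spacing = config.voxel_spacing
    times = config.frame_times()
    aif = config.aif_params

    geom = config.lesion_geometry
    gt_masks = {
        name: rasterize_ellipsoid(geom.ellipsoid(name), shape, spacing)
        for name in ("core_inner", "core_outer", "hypo_inner", "hypo_outer")
    }
    prior_mask = (
        rasterize_ellipsoid(config.prior_infarct, shape, spacing)
        if config.prior_infarct is not None
        else np.zeros(shape, dtype=bool)
    )
    if (prior_mask & gt_masks["hypo_outer"]).any():
        raise GeometryError("prior-infarct ellipsoid overlaps the acute lesion")

    # physiological lesion = mid-surface of each annotation band
    core_phys = rasterize_ellipsoid(geom.mid_core(), shape, spacing)
    hypo_phys = rasterize_ellipsoid(geom.mid_hypo(), shape, spacing)
    penumbra_phys = hypo_phys & ~core_phys

    hd = config.lesion_hemodynamics
    tissue_beta = aif.beta * config.tissue_broadening
    tissue_amp = aif.amplitude * config.tissue_gain

    def tissue_curve(extra_delay: float, reduction: float) -> np.ndarray:
        return TISSUE_BASELINE_HU + gamma_variate(
            times,
            aif.t0 + config.tissue_delay + extra_delay,
            aif.alpha,
            tissue_beta,
            tissue_amp * (1.0 - reduction),
        )

    normal_tac = tissue_curve(0.0, 0.0)
    penumbra_tac = tissue_curve(hd.delay_penumbra, hd.amplitude_reduction_penumbra)
    core_tac = tissue_curve(hd.delay_core, hd.amplitude_reduction_core)
    # chronic infarct: encephalomalacic tissue, hypodense, no bolus passage
    prior_tac = np.full_like(times, TISSUE_BASELINE_HU - 15.0)
    arterial_tac = BLOOD_BASELINE_HU + gamma_variate(
        times, aif.t0, aif.alpha, aif.beta, aif.amplitude
    )
    venous_tac = BLOOD_BASELINE_HU + gamma_variate(
        times,
        aif.t0 + config.venous_delay,
        aif.alpha,
        aif.beta * config.venous_broadening,
        aif.amplitude,
    )

    # vessel ROIs near the posterior midline, away from lesion and mirror
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    z_mid = extent[0] / 2.0
    aif_roi = _sphere_roi((z_mid, extent[1] * 0.1, extent[2] * 0.5), 2.5, shape, spacing)
    venous_roi = _sphere_roi((z_mid, extent[1] * 0.92, extent[2] * 0.5), 2.5, shape, spacing)
    for name, roi in (("arterial", aif_roi), ("venous", venous_roi)):
        if not roi.any():
            raise GeometryError(f"{name} ROI rasterized to zero voxels")
        if (roi & gt_masks["hypo_outer"]).any() or (roi & prior_mask).any():
            raise GeometryError(f"{name} ROI overlaps the lesion; adjust lesion_geometry")
    if (aif_roi & venous_roi).any():
        raise GeometryError("arterial and venous ROIs overlap")

    data = np.empty((config.n_frames,) + shape, dtype=np.float64)
    data[:] = normal_tac[:, None, None, None]
    for mask, tac in (
        (penumbra_phys, penumbra_tac),
        (core_phys, core_tac),
        (prior_mask, prior_tac),
        (aif_roi, arterial_tac),
        (venous_roi, venous_tac),
    ):
        data[:, mask] = tac[:, None]

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    series = PerfusionSeries(data=data, spacing=spacing, frame_times=times)
    gt = UncertainLabel(
        core_inner=gt_masks["core_inner"],
        core_outer=gt_masks["core_outer"],
        hypo_inner=gt_masks["hypo_inner"],
        hypo_outer=gt_masks["hypo_outer"],
        prior_infarct=prior_mask,
        spacing=spacing,
    )

    arterial_peak = int(np.argmax(arterial_tac))
    ncct, cta, mcta, mcta_idx = derive_static_scans(series, arterial_peak, aif.t0)
    return PhantomCase(
        series=series,
        gt=gt,
        aif_roi=aif_roi,
        venous_roi=venous_roi,
        ncct=ncct,
        cta=cta,
        mcta=mcta,
        config=config,
        arterial_peak_index=arterial_peak,
        mcta_frame_indices=mcta_idx,
    )


def derive_static_scans(
    series: PerfusionSeries, arterial_peak: int, contrast_onset: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Derive NCCT, CTA and mCTA volumes from the perfusion series.

    NCCT is the mean of all frames acquired before contrast onset (the first
    frame if none precede it); CTA is the frame at the arterial peak; mCTA
    consists of the arterial-peak frame plus frames 13 s and 21 s later
    (offsets converted with round-half-up, references past the series end
    clamped to the second-last frame).
    """
    n = series.n_frames
    if not 0 <= arterial_peak < n:
        raise ConfigError(f"arterial peak frame {arterial_peak} outside series (0..{n - 1})")
    pre = series.frame_times < contrast_onset
    ncct = series.data[pre].mean(axis=0) if pre.any() else series.data[0].copy()
    cta = series.data[arterial_peak].copy()
    interval = series.frame_interval
    idx = [arterial_peak] + [
        arterial_peak + seconds_to_frames(d, interval) for d in MCTA_PHASE_DELAYS_S
    ]
    idx = [min(i, n - 2) for i in idx]
    mcta = series.data[idx].copy()
    return ncct, cta, mcta, tuple(idx)


# ---------------------------------------------------------------------------
# on-disk case layout


def _config_to_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    return d


def _config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    d["aif_params"] = AifParams(**d["aif_params"])
    geom = dict(d["lesion_geometry"])
    d["lesion_geometry"] = LesionGeometry(
        center=tuple(geom["center"]),
        core_inner=tuple(geom["core_inner"]),
        core_outer=tuple(geom["core_outer"]),
        hypo_inner=tuple(geom["hypo_inner"]),
        hypo_outer=tuple(geom["hypo_outer"]),
    )
    d["lesion_hemodynamics"] = LesionHemodynamics(**d["lesion_hemodynamics"])
    if d.get("prior_infarct") is not None:
        pi = d["prior_infarct"]
        d["prior_infarct"] = Ellipsoid(tuple(pi["center"]), tuple(pi["semi_axes"]))
    d["grid_shape"] = tuple(d["grid_shape"])
    d["voxel_spacing"] = tuple(d["voxel_spacing"])
    return PhantomConfig(**d)


def write_case(case: PhantomCase, directory: str | Path) -> None:
    """Write one case as uncompressed NIfTI volumes plus a config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = case.series.spacing
    # 4D series stored with time as the trailing axis
    _nifti.write_volume(directory / "ctp4d.nii.gz", np.moveaxis(case.series.data, 0, -1), sp)
    _nifti.write_volume(directory / "ncct.nii.gz", case.ncct, sp)
    _nifti.write_volume(directory / "cta.nii.gz", case.cta, sp)
    for i in range(3):
        _nifti.write_volume(directory / f"mcta_phase{i + 1}.nii.gz", case.mcta[i], sp)
    for name, mask in case.gt.masks().items():
        fname = "prior_infarct.nii.gz" if name == "prior_infarct" else f"label_{name}.nii.gz"
        _nifti.write_volume(directory / fname, mask, sp)
    _nifti.write_volume(directory / "roi_aif.nii.gz", case.aif_roi, sp)
    _nifti.write_volume(directory / "roi_venous.nii.gz", case.venous_roi, sp)
    meta = {
        "config": _config_to_dict(case.config),
        "frame_times": [float(t) for t in case.series.frame_times],
        "arterial_peak_index": case.arterial_peak_index,
        "mcta_frame_indices": list(case.mcta_frame_indices),
    }
    with open(directory / "config.yaml", "w") as fh:
        # json round-trip turns tuples into plain lists for the safe dumper
        yaml.safe_dump(json.loads(json.dumps(meta)), fh, sort_keys=False)


def read_case(directory: str | Path) -> PhantomCase:
    """Read a case directory written by :func:`write_case`."""
    directory = Path(directory)
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise FormatError(f"missing sidecar config file: {cfg_path}")
    with open(cfg_path) as fh:
        meta = yaml.safe_load(fh)
    try:
        config = _config_from_dict(meta["config"])
        frame_times = np.asarray(meta["frame_times"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed sidecar config file {cfg_path}: {exc}") from exc

    data4d, spacing = _nifti.read_volume(directory / "ctp4d.nii.gz")
    if data4d.ndim != 4:
        raise FormatError(f"{directory / 'ctp4d.nii.gz'} is not a 4D series")
    series = PerfusionSeries(
        data=np.moveaxis(data4d, -1, 0), spacing=spacing, frame_times=frame_times
    )
    ncct, _ = _nifti.read_volume(directory / "ncct.nii.gz")
    cta, _ = _nifti.read_volume(directory / "cta.nii.gz")
    mcta = np.stack(
        [_nifti.read_volume(directory / f"mcta_phase{i + 1}.nii.gz")[0] for i in range(3)]
    )
    masks = {
        name: _nifti.read_volume(
            directory
            / ("prior_infarct.nii.gz" if name == "prior_infarct" else f"label_{name}.nii.gz"),
            mask=True,
        )[0]
        for name in ("core_inner", "core_outer", "hypo_inner", "hypo_outer", "prior_infarct")
    }
    gt = UncertainLabel(spacing=spacing, **masks)
    aif_roi, _ = _nifti.read_volume(directory / "roi_aif.nii.gz", mask=True)
    venous_roi, _ = _nifti.read_volume(directory / "roi_venous.nii.gz", mask=True)
    return PhantomCase(
        series=series,
        gt=gt,
        aif_roi=aif_roi,
        venous_roi=venous_roi,
        ncct=ncct,
        cta=cta,
        mcta=mcta,
        config=config,
        arterial_peak_index=int(meta["arterial_peak_index"]),
        mcta_frame_indices=tuple(meta["mcta_frame_indices"]),
    )
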