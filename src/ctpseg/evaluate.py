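"""Uncertainty-aware evaluation of nested-contour segmentations.

A prediction arrives, like the ground truth, as a nested inner/outer mask
pair. The pair is collapsed to a one-parameter family of crisp masks through
a *relative distance map*: the Euclidean distance transform (honouring
anisotropic voxel spacing, in mm) gives each voxel in the uncertainty band
its distance ``d_in`` to the inner region and ``d_out`` to the outer
boundary surface, and

    d_r = d_out / (d_out + d_in)

so ``d_r = 1`` on the inner region, ``d_r = 0`` outside the outer region,
and thresholding at ``tau`` yields nested iso-contours that sweep from the
outer contour (``tau = 0``) to the inner contour (``tau = 1``).

A crisp prediction ``A`` is scored against ground-truth inner/outer masks
``B_I, B_O`` with the modified Dice

    D(A, B_I, B_O) = 2 |A ∩ B_O| / (|A| + |B_I| + |A ∩ (B_O \\ B_I)|)

which treats prediction inside the ground-truth outer contour as
non-penalised excess: ``D = 1`` exactly when ``B_I ⊆ A ⊆ B_O``, and it
reduces to the standard Dice coefficient when ``B_I = B_O``. The suite also
decomposes volumes into correct / missing / excess (mL), computes the
average symmetric surface distance (ASSD, mm) between the predicted surface
and the union of the annotated inner and outer contours, selects the best
threshold by mean modified Dice across cases, assigns lesion-volume
subgroups (<1 mL excluded; 1-10, 10-70, >70 mL), and compares pipelines with
exact two-sided Wilcoxon signed-rank tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .errors import ConfigError, LabelValidationError, PairingError

__all__ = [
    "RelativeDistanceMap",
    "CaseEvaluation",
    "ModelComparison",
    "PairResult",
    "ThresholdSweep",
    "relative_distance_map",
    "iso_contour",
    "modified_dice",
    "volume_decomposition",
    "extract_surface",
    "assd",
    "best_threshold",
    "subgroup_assign",
    "compare_models",
    "evaluate_case",
    "DEFAULT_TAU_GRID",
    "SUBGROUP_EXCLUDED",
    "SUBGROUP_SMALL",
    "SUBGROUP_MEDIUM",
    "SUBGROUP_LARGE",
]

DEFAULT_TAU_GRID: np.ndarray = np.round(np.arange(0.0, 1.0001, 0.05), 2)

SUBGROUP_EXCLUDED = "excluded(<1)"
SUBGROUP_SMALL = "1-10"
SUBGROUP_MEDIUM = "10-70"
SUBGROUP_LARGE = ">70"

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_mask(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.ndim != 3:
        raise ConfigError(f"{name} must be a 3D mask; got {m.ndim}D")
    return m


def _check_nested(inner: np.ndarray, outer: np.ndarray) -> None:
    bad = int(np.sum(inner & ~outer))
    if bad:
        raise LabelValidationError(
            f"inner mask is not contained in outer mask ({bad} offending voxels)"
        )


@dataclass
class RelativeDistanceMap:
    """Voxelwise relative position inside an inner/outer uncertainty band."""

    values: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    spacing: tuple[float, float, float]


def extract_surface(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: mask voxels with a face-adjacent neighbour outside.

    Voxels on the array border count as surface (the outside of the array is
    treated as background).
    """
    mask = _as_mask(mask, "mask")
    if not mask.any():
        raise ConfigError("cannot extract the surface of an empty mask")
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE, border_value=0)
    return mask & ~eroded


def relative_distance_map(
    inner: np.ndarray, outer: np.ndarray, spacing: tuple[float, float, float]
) -> RelativeDistanceMap:
    """Build the relative distance map of a nested inner/outer mask pair.

    Distances are physical (mm), anisotropy-aware: ``d_in`` is the distance
    to the inner region, ``d_out`` the distance to the surface voxels of the
    outer mask.
    """
    inner = _as_mask(inner, "inner")
    outer = _as_mask(outer, "outer")
    if inner.shape != outer.shape:
        raise ConfigError(f"inner/outer shapes differ: {inner.shape} vs {outer.shape}")
    if not outer.any():
        raise ConfigError("outer mask is empty")
    _check_nested(inner, outer)
    spacing = tuple(float(s) for s in spacing)

    values = np.zeros(inner.shape, dtype=np.float64)
    if inner.any():
        if np.array_equal(inner, outer):
            values[inner] = 1.0
        else:
            d_in = ndimage.distance_transform_edt(~inner, sampling=spacing)
            outer_surface = extract_surface(outer)
            d_out = ndimage.distance_transform_edt(~outer_surface, sampling=spacing)
            tube = outer & ~inner
            values[tube] = d_out[tube] / (d_out[tube] + d_in[tube])
            values[inner] = 1.0
    # empty inner: the band carries no interior evidence; d_r stays 0 on the
    # tube so tau=1 recovers the (empty) inner mask and tau=0 the outer mask
    return RelativeDistanceMap(values=values, inner=inner.copy(), outer=outer.copy(), spacing=spacing)


def iso_contour(dmap: RelativeDistanceMap, tau: float) -> np.ndarray:
    """Threshold the relative distance map: ``{d_r >= tau}`` within the outer mask.

    ``tau = 0`` recovers the outer mask, ``tau = 1`` the inner mask; the
    family is nested (larger tau, smaller mask).
    """
    if not 0.0 <= tau <= 1.0:
        raise ConfigError(f"tau must lie in [0, 1]; got {tau}")
    return dmap.outer & (dmap.values >= tau)


def modified_dice(a: np.ndarray, b_inner: np.ndarray, b_outer: np.ndarray) -> float:
    """Uncertainty-aware Dice of prediction ``a`` against a nested GT pair.

    Prediction inside the outer contour is never penalised; the score is 1
    exactly when the prediction covers the inner contour and stays within
    the outer one. Empty-set conventions: both ``a`` and ``b_outer`` empty
    gives 1.0; exactly one of them empty gives 0.0.
    """
    a = _as_mask(a, "prediction")
    b_inner = _as_mask(b_inner, "gt inner")
    b_outer = _as_mask(b_outer, "gt outer")
    _check_nested(b_inner, b_outer)
    n_a = int(a.sum())
    n_bi = int(b_inner.sum())
    overlap = int((a & b_outer).sum())
    tube_overlap = int((a & b_outer & ~b_inner).sum())
    denom = n_a + n_bi + tube_overlap
    if denom == 0:
        return 1.0 if not b_outer.any() else 0.0
    return 2.0 * overlap / denom


def volume_decomposition(
    a: np.ndarray,
    b_inner: np.ndarray,
    b_outer: np.ndarray,
    spacing: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Correct / missing / excess volume in mL.

    Correct: prediction inside the outer contour. Missing: inner-contour
    voxels left unpredicted. Excess: prediction outside the outer contour.
    """
    a = _as_mask(a, "prediction")
    b_inner = _as_mask(b_inner, "gt inner")
    b_outer = _as_mask(b_outer, "gt outer")
    _check_nested(b_inner, b_outer)
    v = float(np.prod(spacing)) / 1000.0
    correct = int((a & b_outer).sum()) * v
    missing = int((b_inner & ~a).sum()) * v
    excess = int((a & ~b_outer).sum()) * v
    return correct, missing, excess


def _surface_coords(surface: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    return np.argwhere(surface) * np.asarray(spacing, dtype=float)


def assd(
    surface_a: np.ndarray,
    surface_b: np.ndarray,
    spacing: tuple[float, float, float],
) -> float:
    """Average symmetric surface distance between two surface voxel sets, mm."""
    surface_a = _as_mask(surface_a, "surface_a")
    surface_b = _as_mask(surface_b, "surface_b")
    if not surface_a.any() or not surface_b.any():
        raise ConfigError("ASSD is undefined for an empty surface")
    pa = _surface_coords(surface_a, spacing)
    pb = _surface_coords(surface_b, spacing)
    d_ab = cKDTree(pb).query(pa, workers=1)[0]
    d_ba = cKDTree(pa).query(pb, workers=1)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


@dataclass
class ThresholdSweep:
    """Result of a threshold sweep: the grid, mean scores and the winner."""

    taus: np.ndarray
    mean_dice: np.ndarray
    tau_star: float


def best_threshold(
    case_maps: Sequence[tuple[RelativeDistanceMap, tuple[np.ndarray, np.ndarray]]],
    tau_grid: Sequence[float] | None = None,
) -> ThresholdSweep:
    """Pick the threshold maximising mean modified Dice across cases.

    ``case_maps`` pairs each prediction's relative distance map with the
    case's ground-truth ``(inner, outer)`` masks. Ties are broken towards
    0.5, then towards the smaller threshold.
    """
    taus = np.asarray(DEFAULT_TAU_GRID if tau_grid is None else tau_grid, dtype=float)
    if taus.size == 0:
        raise ConfigError("tau grid is empty")
    if np.any((taus < 0) | (taus > 1)):
        raise ConfigError("tau grid must lie within [0, 1]")
    if len(case_maps) == 0:
        raise ConfigError("at least one case is required")
    scores = np.empty((len(case_maps), taus.size))
    for i, (dmap, (b_inner, b_outer)) in enumerate(case_maps):
        for j, tau in enumerate(taus):
            scores[i, j] = modified_dice(iso_contour(dmap, tau), b_inner, b_outer)
    mean_dice = scores.mean(axis=0)
    best = mean_dice.max()
    candidates = taus[mean_dice >= best - 1e-12]
    tau_star = float(min(candidates, key=lambda t: (abs(t - 0.5), t)))
    return ThresholdSweep(taus=taus, mean_dice=mean_dice, tau_star=tau_star)


def subgroup_assign(gt_volume_ml: float) -> str:
    """Assign the lesion-volume subgroup (half-open intervals, <1 mL excluded)."""
    if gt_volume_ml < 0:
        raise ConfigError(f"volume must be non-negative; got {gt_volume_ml}")
    if gt_volume_ml < 1.0:
        return SUBGROUP_EXCLUDED
    if gt_volume_ml < 10.0:
        return SUBGROUP_SMALL
    if gt_volume_ml < 70.0:
        return SUBGROUP_MEDIUM
    return SUBGROUP_LARGE


@dataclass
class CaseEvaluation:
    """Per-case scores of one pipeline at one threshold."""

    modified_dice: float
    correct_ml: float
    missing_ml: float
    excess_ml: float
    assd_mm: float  # NaN when either surface is empty (undefined case)
    threshold: float
    gt_volume_ml: float
    pred_volume_ml: float
    subgroup: str


def evaluate_case(
    pred_inner: np.ndarray,
    pred_outer: np.ndarray,
    gt_inner: np.ndarray,
    gt_outer: np.ndarray,
    spacing: tuple[float, float, float],
    tau: float = 0.5,
) -> CaseEvaluation:
    """Score a nested prediction pair against a nested ground-truth pair.

    The prediction pair is collapsed at threshold ``tau`` via its relative
    distance map; the ground-truth volume used for subgrouping is the
    tau=0.5 iso-region of the ground-truth pair (symmetric treatment of both
    band representations).
    """
    voxel_ml = float(np.prod(spacing)) / 1000.0
    if gt_outer.any():
        gt_map = relative_distance_map(gt_inner, gt_outer, spacing)
        gt_mid = iso_contour(gt_map, 0.5)
    else:
        gt_mid = np.zeros(np.asarray(gt_outer).shape, dtype=bool)
    gt_volume_ml = float(gt_mid.sum()) * voxel_ml

    if pred_outer.any():
        pred_map = relative_distance_map(pred_inner, pred_outer, spacing)
        a = iso_contour(pred_map, tau)
    else:
        a = np.zeros(gt_inner.shape, dtype=bool)
    dice = modified_dice(a, gt_inner, gt_outer)
    correct, missing, excess = volume_decomposition(a, gt_inner, gt_outer, spacing)
    if a.any() and gt_outer.any():
        gt_surface = extract_surface(gt_outer)
        if gt_inner.any():
            gt_surface = gt_surface | extract_surface(gt_inner)
        assd_mm = assd(extract_surface(a), gt_surface, spacing)
    else:
        assd_mm = float("nan")
    return CaseEvaluation(
        modified_dice=dice,
        correct_ml=correct,
        missing_ml=missing,
        excess_ml=excess,
        assd_mm=assd_mm,
        threshold=float(tau),
        gt_volume_ml=gt_volume_ml,
        pred_volume_ml=float(a.sum()) * voxel_ml,
        subgroup=subgroup_assign(gt_volume_ml),
    )


@dataclass
class PairResult:
    """Wilcoxon signed-rank comparison of two paired pipelines."""

    model_a: str
    model_b: str
    n: int
    p_raw: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False  # all paired differences were zero


@dataclass
class ModelComparison:
    pairs: list[PairResult] = field(default_factory=list)
    n_comparisons: int = 0
    alpha: float = 0.05


def compare_models(
    scores: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ModelComparison:
    """Pairwise two-sided Wilcoxon signed-rank tests with Bonferroni correction.

    ``scores`` maps pipeline name to its per-case score vector; all vectors
    must be paired over the identical case set. Zero differences are dropped
    (Wilcoxon's classic treatment); the exact null distribution is used for
    up to 25 non-zero differences, the normal approximation with continuity
    correction beyond. The Bonferroni factor is the number of pairs tested;
    an all-zero difference vector is reported as p = 1 with a degenerate
    flag.
    """
    names = list(scores)
    if len(names) < 2:
        raise ConfigError("need at least two pipelines to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    n_cases = {k: a.shape for k, a in arrays.items()}
    if len(set(n_cases.values())) != 1:
        raise PairingError(f"pipelines are not paired over identical case sets: {n_cases}")
    n = arrays[names[0]].size
    if n < 5:
        raise ConfigError(f"need at least 5 paired cases; got {n}")

    pairs = list(combinations(names, 2))
    comparison = ModelComparison(n_comparisons=len(pairs), alpha=alpha)
    for a_name, b_name in pairs:
        diff = arrays[a_name] - arrays[b_name]
        nonzero = diff[diff != 0]
        if nonzero.size == 0:
            p_raw, degenerate = 1.0, True
        else:
            method = "exact" if nonzero.size <= 25 else "approx"
            res = stats.wilcoxon(
                nonzero,
                zero_method="wilcox",
                alternative="two-sided",
                correction=(method == "approx"),
                method=method,
            )
            p_raw, degenerate = float(res.pvalue), False
        p_adj = min(1.0, p_raw * len(pairs))
        comparison.pairs.append(
            PairResult(
                model_a=a_name,
                model_b=b_name,
                n=n,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
                degenerate=degenerate,
            )
        )
    return comparison
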