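"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: generate a seeded phantom
cohort, derive the per-scenario network-input data (NCCT / CTA / mCTA /
CTP, the latter optionally through a temporal-sampling strategy), run the
stand-in segmenter, evaluate every case with the uncertainty-aware suite,
and aggregate subgroup tables plus pairwise Wilcoxon/Bonferroni
comparisons into a report.

The stand-in segmenter thresholds per-voxel hemodynamic summary maps, so
each scenario feeds it the frames that scenario makes available: the single
NCCT volume carries no temporal contrast information at all (its prediction
is empty by construction), CTA adds one arterial snapshot, mCTA three timed
phases, and CTP scenarios the perfusion frames. A CTP scenario without a
timing strategy uses the full native series — the analogue of computing
perfusion maps from the complete acquisition; with a strategy it uses the
averaged phase stack that strategy selects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .evaluate import (
    SUBGROUP_EXCLUDED,
    best_threshold,
    compare_models,
    evaluate_case,
    iso_contour,
    relative_distance_map,
)
from .labels import SegmenterThresholds, UncertainLabel, proxy_maps, standin_segment
from .phantom import (
    Ellipsoid,
    LesionGeometry,
    LesionHemodynamics,
    PhantomCase,
    PhantomConfig,
    make_phantom,
    write_case,
)
from .series import PerfusionSeries
from .timing import (
    apply_plan,
    extract_tac,
    plan_equidistant,
    plan_fixed_mcta,
    plan_peak,
    plan_varying_mcta,
)

__all__ = [
    "CohortConfig",
    "ScenarioConfig",
    "EvaluationSettings",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
]

logger = logging.getLogger(__name__)

INPUT_TYPES = ("NCCT", "CTA", "mCTA", "CTP")
STRATEGIES = ("fixed_mcta", "varying_mcta", "peak", "peak_baseline", "equidistant")


@dataclass
class CohortConfig:
    """Randomized phantom cohort: per-case lesion size/position/hemodynamics.

    Ranges are sampled uniformly per case; the base lesion geometry is the
    package default scaled by ``radius_scale`` and shifted by up to
    ``center_jitter_mm`` in-plane.
    """

    n_cases: int = 20
    seed: int = 0
    grid_shape: tuple[int, int, int] = (16, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    n_frames: int = 30
    frame_interval: float = 1.5
    noise_sd: float = 0.0
    radius_scale: tuple[float, float] = (0.85, 1.15)
    center_jitter_mm: float = 3.0
    reduction_core: tuple[float, float] = (0.55, 0.70)
    reduction_penumbra: tuple[float, float] = (0.25, 0.35)
    delay_core: tuple[float, float] = (3.0, 5.0)
    delay_penumbra: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError(f"n_cases must be >= 1; got {self.n_cases}")

    def sample_case_configs(self) -> list[PhantomConfig]:
        rng = np.random.default_rng(self.seed)
        base = LesionGeometry()
        # anchor the lesion to the grid: mid-slice, mid-coronal, lateralised
        # to one hemisphere so the mirrored contralateral tissue stays normal
        extent = tuple((n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing))
        anchor = (extent[0] / 2.0, extent[1] / 2.0, extent[2] * 0.32)
        configs = []
        for _ in range(self.n_cases):
            scale = rng.uniform(*self.radius_scale)
            jitter = rng.uniform(-self.center_jitter_mm, self.center_jitter_mm, size=2)
            center = (anchor[0], anchor[1] + jitter[0], anchor[2] + jitter[1])
            geom = LesionGeometry(
                center=center,
                core_inner=tuple(s * scale for s in base.core_inner),
                core_outer=tuple(s * scale for s in base.core_outer),
                hypo_inner=tuple(s * scale for s in base.hypo_inner),
                hypo_outer=tuple(s * scale for s in base.hypo_outer),
            )
            hemo = LesionHemodynamics(
                amplitude_reduction_core=rng.uniform(*self.reduction_core),
                amplitude_reduction_penumbra=rng.uniform(*self.reduction_penumbra),
                delay_core=rng.uniform(*self.delay_core),
                delay_penumbra=rng.uniform(*self.delay_penumbra),
            )
            configs.append(
                PhantomConfig(
                    grid_shape=tuple(self.grid_shape),
                    voxel_spacing=tuple(self.voxel_spacing),
                    n_frames=self.n_frames,
                    frame_interval=self.frame_interval,
                    lesion_geometry=geom,
                    lesion_hemodynamics=hemo,
                    noise_sd=self.noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        return configs


@dataclass
class ScenarioConfig:
    """One experiment arm: which CT image type feeds the segmenter."""

    name: str
    input_type: str
    timing_strategy: str | None = None

    def __post_init__(self) -> None:
        if self.input_type not in INPUT_TYPES:
            raise ConfigError(
                f"scenario {self.name!r}: unknown input_type {self.input_type!r}; "
                f"expected one of {INPUT_TYPES}"
            )
        if self.timing_strategy is not None:
            if self.input_type != "CTP":
                raise ConfigError(
                    f"scenario {self.name!r}: timing_strategy applies only to CTP input"
                )
            if self.timing_strategy not in STRATEGIES:
                raise ConfigError(
                    f"scenario {self.name!r}: unknown timing_strategy "
                    f"{self.timing_strategy!r}; expected one of {STRATEGIES}"
                )


@dataclass
class EvaluationSettings:
    tau_report: float = 0.5
    tau_grid_step: float = 0.05
    exclude_below_ml: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_report <= 1.0:
            raise ConfigError(
                f"evaluation.tau_report must lie in [0, 1]; got {self.tau_report}"
            )
        if not 0.0 < self.tau_grid_step <= 1.0:
            raise ConfigError(
                f"evaluation.tau_grid_step must lie in (0, 1]; got {self.tau_grid_step}"
            )

    def tau_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, 1.0 + 1e-9, self.tau_grid_step), 6)


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scenarios: list[ScenarioConfig] = field(
        default_factory=lambda: [
            ScenarioConfig("NCCT", "NCCT"),
            ScenarioConfig("CTA", "CTA"),
            ScenarioConfig("mCTA", "mCTA"),
            ScenarioConfig("CTP", "CTP"),
        ]
    )
    segmenter: SegmenterThresholds = field(default_factory=SegmenterThresholds)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    output_dir: str | None = None
    write_cases: bool = False

    def __post_init__(self) -> None:
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigError(f"scenario names must be unique; got {names}")
        if not self.scenarios:
            raise ConfigError("at least one scenario is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cohort = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in (raw.get("cohort") or {}).items()
            })
            scenarios = [ScenarioConfig(**s) for s in raw.get("scenarios", [])] or None
            segmenter = SegmenterThresholds(**(raw.get("segmenter") or {}))
            evaluation = EvaluationSettings(**(raw.get("evaluation") or {}))
        except TypeError as exc:
            raise ConfigError(f"malformed experiment config {path}: {exc}") from exc
        kwargs = dict(
            cohort=cohort,
            segmenter=segmenter,
            evaluation=evaluation,
            output_dir=raw.get("output_dir"),
            write_cases=bool(raw.get("write_cases", False)),
        )
        if scenarios is not None:
            kwargs["scenarios"] = scenarios
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Per-case table, subgroup summaries, comparisons and provenance."""

    cases: pd.DataFrame
    summary: dict
    comparisons: dict
    provenance: dict
    failures: list[dict] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cases.to_csv(directory / "cases.csv", index=False, float_format="%.6f")
        payload = {
            "summary": self.summary,
            "comparisons": self.comparisons,
            "provenance": self.provenance,
            "failures": self.failures,
        }
        with open(directory / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _scenario_series(case: PhantomCase, scenario: ScenarioConfig) -> PerfusionSeries | None:
    """Assemble the frames a scenario makes available to the segmenter.

    Returns None when the scenario carries no temporal contrast information
    (single-volume NCCT input), in which case the prediction is empty.
    """
    interval = case.series.frame_interval
    if scenario.input_type == "NCCT":
        return None
    if scenario.input_type == "CTA":
        frames = np.stack([case.ncct, case.cta])
        times = np.array([0.0, case.arterial_peak_index * interval])
    elif scenario.input_type == "mCTA":
        frames = np.concatenate([case.ncct[None], case.mcta])
        times = np.array([0.0] + [i * interval for i in case.mcta_frame_indices])
    else:  # CTP
        if scenario.timing_strategy is None:
            return case.series
        aif = extract_tac(case.series, case.aif_roi)
        n = case.series.n_frames
        if scenario.timing_strategy == "fixed_mcta":
            plan = plan_fixed_mcta(aif, interval, n)
        elif scenario.timing_strategy == "varying_mcta":
            plan = plan_varying_mcta(aif, interval, n, rng_seed=case.config.seed)
        elif scenario.timing_strategy == "peak":
            plan = plan_peak(aif, extract_tac(case.series, case.venous_roi), False, n)
        elif scenario.timing_strategy == "peak_baseline":
            plan = plan_peak(aif, extract_tac(case.series, case.venous_roi), True, n)
        else:
            plan = plan_equidistant(n)
        stack = apply_plan(case.series, plan)
        frames = np.concatenate([case.ncct[None], stack.data])
        times = np.concatenate([[0.0], stack.reference_times])
    # drop duplicate time points (possible after window clamping)
    keep = np.concatenate([[True], np.diff(times) > 0])
    return PerfusionSeries(
        data=frames[keep], spacing=case.series.spacing, frame_times=times[keep]
    )


def _segment_scenario(
    case: PhantomCase, scenario: ScenarioConfig, thresholds: SegmenterThresholds
) -> UncertainLabel:
    series = _scenario_series(case, scenario)
    shape = case.series.grid_shape
    spacing = case.series.spacing
    if series is None or series.n_frames < 2:
        return UncertainLabel.empty(shape, spacing)
    if series is case.series:
        onset = case.config.aif_params.t0
        baseline_frames = max(1, int(np.sum(series.frame_times < onset)))
    else:
        baseline_frames = 1
    maps = proxy_maps(series, baseline_frames=baseline_frames)
    return standin_segment(maps, thresholds, spacing)


def _summarize(group: pd.DataFrame) -> dict:
    return {
        "n": int(len(group)),
        "modified_dice_mean": float(group["modified_dice"].mean()),
        "modified_dice_sd": float(group["modified_dice"].std(ddof=1)) if len(group) > 1 else 0.0,
        "correct_ml_mean": float(group["correct_ml"].mean()),
        "missing_ml_mean": float(group["missing_ml"].mean()),
        "excess_ml_mean": float(group["excess_ml"].mean()),
        "assd_mm_mean": float(np.nanmean(group["assd_mm"]))
        if np.isfinite(group["assd_mm"]).any()
        else float("nan"),
        "gt_volume_ml_mean": float(group["gt_volume_ml"].mean()),
        "pred_volume_ml_mean": float(group["pred_volume_ml"].mean()),
        "phys_volume_ml_mean": float(group["phys_volume_ml"].mean()),
        # recovery of the generating lesion volume by the prediction
        "volume_abs_rel_err_mean": float(
            (np.abs(group["pred_volume_ml"] - group["phys_volume_ml"]) / group["phys_volume_ml"]).mean()
        ),
    }


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full generate -> segment -> evaluate -> compare experiment."""
    t_start = time.time()
    case_configs = config.cohort.sample_case_configs()
    tau_report = config.evaluation.tau_report
    tau_grid = config.evaluation.tau_grid()

    rows: list[dict] = []
    failures: list[dict] = []
    sweep_inputs: dict[str, list] = {s.name: [] for s in config.scenarios}
    dice_by_scenario: dict[str, dict[int, float]] = {s.name: {} for s in config.scenarios}

    out_dir = Path(config.output_dir) if config.output_dir else None
    for case_idx, case_config in enumerate(case_configs):
        case_id = f"case_{case_idx:04d}"
        case = make_phantom(case_config)
        if out_dir is not None and config.write_cases:
            write_case(case, out_dir / "cases" / case_id)
        for scenario in config.scenarios:
            t0 = time.time()
            try:
                pred = _segment_scenario(case, scenario, config.segmenter)
                geom = case.config.lesion_geometry
                for cls in ("core", "hypo"):
                    pi, po = pred.class_pair(cls)
                    gi, go = case.gt.class_pair(cls)
                    ev = evaluate_case(pi, po, gi, go, case.gt.spacing, tau=tau_report)
                    mid = geom.mid_core() if cls == "core" else geom.mid_hypo()
                    rows.append(
                        {
                            "case_id": case_id,
                            "scenario": scenario.name,
                            "target": cls,
                            "tau": tau_report,
                            "phys_volume_ml": mid.volume_mm3() / 1000.0,
                            "modified_dice": ev.modified_dice,
                            "correct_ml": ev.correct_ml,
                            "missing_ml": ev.missing_ml,
                            "excess_ml": ev.excess_ml,
                            "assd_mm": ev.assd_mm,
                            "gt_volume_ml": ev.gt_volume_ml,
                            "pred_volume_ml": ev.pred_volume_ml,
                            "subgroup": ev.subgroup,
                        }
                    )
                    if cls == "core":
                        dice_by_scenario[scenario.name][case_idx] = ev.modified_dice
                        if po.any():
                            sweep_inputs[scenario.name].append(
                                (
                                    relative_distance_map(pi, po, case.gt.spacing),
                                    (case.gt.core_inner, case.gt.core_outer),
                                )
                            )
                logger.info(
                    "%s / %s evaluated in %.2f s", case_id, scenario.name, time.time() - t0
                )
            except Exception as exc:  # keep going; report failures
                logger.exception("%s / %s failed", case_id, scenario.name)
                failures.append(
                    {"case_id": case_id, "scenario": scenario.name, "error": str(exc)}
                )

    cases_df = pd.DataFrame(rows)
    summary: dict = {"scenarios": {}, "elapsed_s": None}
    for scenario in config.scenarios:
        df = cases_df[
            (cases_df["scenario"] == scenario.name) & (cases_df["target"] == "core")
        ]
        included = df[df["gt_volume_ml"] >= config.evaluation.exclude_below_ml]
        per_subgroup = {
            str(sub): _summarize(g)
            for sub, g in included.groupby("subgroup")
            if sub != SUBGROUP_EXCLUDED
        }
        sweep = (
            best_threshold(sweep_inputs[scenario.name], tau_grid)
            if sweep_inputs[scenario.name]
            else None
        )
        summary["scenarios"][scenario.name] = {
            "input_type": scenario.input_type,
            "timing_strategy": scenario.timing_strategy,
            "overall": _summarize(included) if len(included) else {"n": 0},
            "subgroups": per_subgroup,
            "n_excluded_below_1ml": int((df["gt_volume_ml"] < config.evaluation.exclude_below_ml).sum()),
            "tau_star": sweep.tau_star if sweep is not None else None,
            "tau_report": tau_report,
        }

    comparisons: dict = {"pairs": [], "n_comparisons": 0}
    common = [
        i
        for i in range(config.cohort.n_cases)
        if all(i in dice_by_scenario[s.name] for s in config.scenarios)
    ]
    if len(config.scenarios) >= 2 and len(common) >= 5:
        paired = {
            s.name: [dice_by_scenario[s.name][i] for i in common] for s in config.scenarios
        }
        mc = compare_models(paired)
        comparisons = {
            "n_comparisons": mc.n_comparisons,
            "alpha": mc.alpha,
            "pairs": [dataclasses.asdict(p) for p in mc.pairs],
        }

    provenance = {
        "config_hash": config.content_hash(),
        "cohort_seed": config.cohort.seed,
        "case_seeds": [c.seed for c in case_configs],
        "package_version": __version__,
        "n_cases": config.cohort.n_cases,
        "scenarios": [s.name for s in config.scenarios],
    }
    summary["elapsed_s"] = round(time.time() - t_start, 3)
    report = ExperimentReport(
        cases=cases_df,
        summary=summary,
        comparisons=comparisons,
        provenance=provenance,
        failures=failures,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
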