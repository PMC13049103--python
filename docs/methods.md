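# Methods

This note documents the models, parameter choices and numerical conventions
behind `ctpseg`, and what the synthetic phantom can and cannot show.

## The phantom

### Enhancement model

Every dynamic curve is a gamma-variate bolus,

    g(t) = A · ((t − t0)/(αβ))^α · exp(α − (t − t0)/β)   for t > t0, else 0,

normalised so its maximum equals `A` and peaking at `t0 + αβ`. The model is
the standard first-pass parameterisation of contrast passage and is used
for four compartments:

| compartment | curve | default |
| --- | --- | --- |
| artery (AIF ROI) | baseline 45 HU + g(t; t0, α, β, A) | t0 = 8 s, α = 3, β = 1.8 s, A = 300 HU |
| vein (reference ROI) | arterial curve delayed and broadened | delay 3.5 s, β × 1.5 |
| normal tissue | baseline 35 HU + attenuated, delayed, dispersed copy | gain 0.12 · A, delay 2 s, β × 2.5 |
| lesion tissue | tissue curve with extra delay and amplitude loss | core: −60 % amplitude, +4 s; penumbra: −30 %, +2 s |

These defaults give an arterial peak ≈ 13.4 s after scan start, a venous
peak ≈ 3 s later, and a broad tissue curve peaking ≈ 22 s — a plausible
ordering and scale for a 44 × 1.5 s (66 s) or 30 × 1.5 s (45 s) perfusion
acquisition. The venous delay/broadening and the tissue delay/dispersion
are separate config fields because realistic time-attenuation curves in
tissue and vein are not shifted copies of the arterial input; the venous
peak must come strictly after the arterial peak for peak-based timing to be
well defined (the planner raises an error otherwise). Noise is i.i.d.
Gaussian per voxel and frame (default 2 HU; study cohorts in the tests and
acceptance run are generated noise-free so that every discrepancy is
attributable to the algorithms, not the noise realisation).

### Geometry and ground truth

The lesion is four nested axis-aligned ellipsoids sharing one centre:
inner/outer core within inner/outer hypoperfused volume. The *annotation
band* between each inner/outer pair models rater uncertainty; the
*physiological* lesion — the region whose curves are actually altered — is
the mid-surface ellipsoid of each band (semi-axes averaged). A perfect
segmenter therefore lands inside the band, which is exactly the situation
the band-aware metrics are built for, and "parameter recovery" has a
well-defined target: the mid-band ellipsoid volume. An optional prior
infarct is a disjoint ellipsoid of flat hypodense tissue (no bolus
passage), mutually exclusive with the acute lesion by construction (overlap
is a geometry error).

Default semi-axes (z, y, x in mm): core 5/8/8 → 7/10/10, hypoperfusion
9/13/12 → 11/16/14 on a 16 × 64 × 64 grid with 2 × 1 × 1 mm spacing; the
mid-band core is ≈ 2.0 mL, i.e. the 1–10 mL subgroup that dominates real
cohorts. Cohort sampling scales all four shells by a common factor
(default 0.85–1.15) and jitters the centre in-plane, which preserves strict
nesting by construction.

### What the phantom does not emulate

No skull or beam hardening, no patient motion (volumes are generated
co-registered, i.e. the post-registration state of a clinical pipeline), no
partial-volume or photon-starvation artifacts, no vascular tree beyond two
spherical reference ROIs, and no deconvolution-based perfusion maps.
Passing tests on the phantom therefore demonstrate the correctness of the
*computational machinery* — timing arithmetic, label algebra, metrics,
statistics — not robustness of any segmenter to clinical image quality.

## Temporal sampling

All strategies resolve to reference frames with 3-frame averaging windows
(reference ± 1). Conventions the sources of the protocol leave open were
fixed as follows:

* Seconds-to-frames conversion rounds half up: 13 s at 1.5 s/frame → 9
  frames, 21 s → 14 frames. Deterministic and symmetric around the phase
  spacing.
* "Second-last time point before the peak" is read literally as
  `t_Amax − 2`.
* The varying-mCTA offset δ is a discrete uniform draw from {−5, …, +2}
  frames, reproducible from an integer seed.
* If the final window would run past the series, its reference is reset to
  the second-last frame (window = last three frames). The mirrored rule
  holds at the series start (reference raised to frame 1). Clamping is
  applied to any overflowing phase — only the final phase can overflow in
  practice — and every adjusted phase carries a `clamped` flag.
* Equidistant sampling always uses frames 0–23 (eight disjoint windows),
  regardless of series length, because a network input needs a fixed
  channel count and 25 frames is the shortest series the generator accepts.

## Proxy maps and the stand-in segmenter

The stand-in replaces a trained segmentation network with thresholds on
three per-voxel summary maps: AUC (trapezoidal integral of the positive
baseline-subtracted signal, HU·s), time-to-peak (s) and maximum slope
(HU/s). These are deliberately *not* presented as CBV/CBF/TMAX — no
deconvolution is performed; they merely carry the same qualitative
contrast (less and later enhancement inside the lesion).

Segmentation rule: a voxel is hypoperfused when its time-to-peak delay
(relative to the volume-median reference) exceeds the delay threshold —
counted only where a bolus actually passes, i.e. AUC above 10 % of the
reference AUC, since arrival time is meaningless without arrival — or when
its fractional AUC deficit exceeds the hypoperfusion deficit threshold.
The deficit branch is what lets static inputs (CTA, mCTA phases) carry
signal at all: with one to three post-contrast samples a time-to-peak is
too coarse to detect a 2–4 s delay, but the enhancement deficit survives
sparse sampling. Core additionally requires a deep deficit (lenient 0.42 /
strict 0.50, bracketing the default core amplitude loss of 0.55–0.70 from
above the penumbra loss of 0.25–0.35). Strict thresholds produce the inner
contour, lenient the outer, so nesting holds by construction; morphological
closing (1 voxel) and removal of components below 0.1 mL are the
automatable analogue of a rater's compactness cleanup, and a final
intersection pass re-imposes nesting after morphology. The prediction's
prior-infarct channel is always empty — the stand-in has no model for
chronic infarcts.

The segmenter is pluggable: externally produced predictions in the same
inner/outer NIfTI mask format drop into the evaluation unchanged.

## Evaluation conventions

* **Relative distance map.** `d_in` is the Euclidean distance (mm,
  anisotropy-aware) to the inner *region*, `d_out` to the *surface voxels*
  of the outer mask; `d_r = d_out/(d_out + d_in)` on the band, 1 on the
  inner region, 0 outside the outer. This matches the hand computation on
  a 1-mm slab (a voxel 2 mm from each boundary gets 0.5). Consequence of
  the discrete convention: outer-surface voxels carry `d_r = 0`, so any
  τ > 0 excludes the one-voxel outer rim, and the τ = 0.5 iso-region of a
  band sits roughly half a voxel inside the continuous mid-surface.
  `iso_contour` at τ = 0 returns the outer mask exactly, at τ = 1 the
  inner mask.
* **Volume for subgrouping and exclusion** is the τ = 0.5 iso-region of
  the *ground-truth* pair (symmetric with prediction handling); cases
  below 1 mL are excluded from subgroup summaries. Volume *recovery*, by
  contrast, is measured against the configured mid-band ellipsoid volume —
  the generating parameter — because the τ = 0.5 GT region carries the
  half-voxel discretisation bias above (≈ 15 % for a 2-mL lesion on 2-mm
  slices), which is a property of the grid, not of the segmentation.
* **Modified Dice empty-set conventions**: prediction and outer contour
  both empty → 1.0; exactly one of them empty → 0.0 (limit-consistent with
  the standard Dice conventions).
* **Subgroup boundaries** are half-open: [1, 10), [10, 70), [70, ∞) mL.
* **ASSD** uses surface voxels (6-connectivity, array border counts as
  outside) in physical mm via KD-trees; the ground-truth surface is the
  union of the inner and outer contour surfaces. It is undefined (NaN)
  when either surface is empty.
* **Threshold sweep** over τ ∈ {0, 0.05, …, 1}; ties in mean modified Dice
  break towards 0.5, then towards the smaller τ.
* **Wilcoxon signed-rank**: two-sided, zero differences dropped, exact
  null distribution up to 25 non-zero differences, normal approximation
  with continuity correction beyond; an all-zero difference vector reports
  p = 1 with a degenerate flag. Bonferroni multiplies by the number of
  pairs actually tested, capped at 1.

## Experiment orchestration

Each scenario feeds the stand-in the frames it makes available: NCCT alone
carries no temporal information (its prediction is empty by construction);
CTA contributes the pre-contrast volume plus the arterial-peak frame; mCTA
its three timed phases; a CTP scenario the full native series, or — when a
timing strategy is named — the pre-contrast volume plus that strategy's
averaged phase stack at the reference times. Feeding the *full* series to
the plain-CTP scenario mirrors how perfusion summary maps are computed in
practice (from the complete acquisition), and makes plain CTP the
upper-bound arm of the modality comparison. Cross-validation folds and
site-transfer fine-tuning are not emulated: the stand-in has no training
phase, so evaluation is a single pass; a two-cohort config with different
phantom parameter ranges is only an *analogue* of a site-transfer setup.

The standard desk-scale experiment (used by the tests and the acceptance
script) is 20 noise-free cases on 16 × 64 × 64 grids with 30-frame series —
large enough that rasterisation error of a ≈ 2 mL core stays ≈ 1 % and every
stage is exercised, small enough to run in seconds. Reports are
deterministic given the config (byte-identical CSV across reruns) and carry
a config hash, the cohort seed and all per-case seeds.

## Known limitations

* The stand-in's thresholds are calibrated to the phantom's hemodynamic
  parameter ranges; on real perfusion data they would need re-tuning, and
  nothing here claims network-level performance.
* Rigid registration is out of scope; the `resample_to_grid` hook accepts
  an externally computed rigid transform but none is estimated.
* The phantom's contrast amplitudes are free parameters, not calibrated to
  any particular display windowing.
* With lesions much smaller than a voxel-slab (≲ 0.5 mL on 2-mm slices)
  the discrete band degenerates and band metrics lose meaning; such cases
  are precisely what the < 1 mL exclusion removes.
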