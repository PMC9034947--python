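# Methods

`corogrow` segments the coronary lumen in contrast-enhanced cardiac CT
volumes by chaining four stages: intensity windowing, multiscale Hessian
vesselness, automatic seed localization at the aorta–coronary junction, and
vesselness-gated seeded region growing. This note records the model behind
each stage, the parameters that matter, the synthetic phantoms the package is
validated on, and the numerical choices made where the design was open.

## Intensity windowing

Coronary CTA working intensities lie in roughly 0–600 HU; contrast-filled
lumen is ~300–450 HU while surrounding soft tissue sits below ~100 HU. The
window/level transform with level `wl = 300` HU and width `ww = 600` HU maps
this range piecewise-linearly onto [0, 255]:

```
y = 0                          x ∈ [0, wl − ww/2)
y = 128 + 256 (x − wl)/ww      x ∈ [wl − ww/2, wl + ww/2)
y = 255                        x ∈ [wl + ww/2, 600]
```

Inputs are clamped to [0, 600] first and the output to [0, `clamp_max`]
(default 255). At the right edge of the linear branch the formula approaches
256, so the final clamp is load-bearing; we keep the literal piecewise form
plus the clamp rather than rescaling the slope. Output values stay floating
point by default so the differential filters downstream lose no precision; an
integer-quantize flag exists for export only. Intervals are half-open on the
right: a voxel exactly at `wl + ww/2` takes the saturated value 255.

## Multiscale Hessian vesselness

At each scale `α` (Gaussian sd, in voxels) the enhanced volume is convolved
with Gaussian second-derivative kernels (smoothing and differentiation fused;
reflect boundaries), yielding the symmetric 3×3 Hessian per voxel. With
γ-normalization each component is multiplied by `α²`, which makes magnitudes
comparable across scales.

Eigenvalues are ordered by ascending magnitude, `|β₁| ≤ |β₂| ≤ |β₃|`. Inside
a bright tube, β₁ ≈ 0 along the axis and β₂ ≈ β₃ ≪ 0 radially; the
eigenvector of β₁ is tangential. (Descriptions of this decomposition
sometimes order by signed value with the near-zero eigenvalue listed last;
the magnitude ordering used here is the standard convention for tubular
filters and is what all formulas below assume.)

Three geometric ratios feed the score:

- `R_A = |β₂|/|β₃|` — distinguishes plates (`R_A → 0`) from lines
  (`R_A → 1`);
- `R_B = |β₁|/√|β₂β₃|` — distinguishes blobs (`R_B → 1`) from lines
  (`R_B → 0`); the geometric-mean denominator keeps the ratio dimensionless;
- `S = √(β₁² + β₂² + β₃²)` — the Frobenius norm of the Hessian, a
  contrast-dependent structure strength. The radical matters: with it, the
  associated threshold is in eigenvalue units.

With `U₁ = exp(−R_A²/2ε²)`, `U₂ = exp(−R_B²/2ϕ²)`, `U₃ = exp(−S²/2φ²)`,
the single-scale vesselness is

```
V = (1 − U₁) · U₂ · (1 − U₃)
```

zeroed wherever β₂ > 0 or β₃ > 0 (bright structures curve downward in
intensity; a `bright_vessels=False` switch flips the test for dark vessels).
This grouping is the only one of the three-factor product that is maximal for
tubes and vanishes for plates (through 1−U₁), blobs (through U₂) and
low-contrast noise (through 1−U₃). V ∈ [0, 1] by construction.

Scale fusion is the voxelwise maximum over the scale list (default
`{0.5, 1, 2}` voxels, matching coronary radii of ~0.5–3 voxels at the
phantom resolution). Under γ-normalization the maximizing scale tracks the
vessel radius; on hard-edged tube phantoms of radius 1, 2 and 3 voxels the
argmax scale over `{0.5, 1, 2, 3}` equals the radius.

Parameter defaults: `ε = 0.5`, `ϕ = 0.5` (the customary half-value for the
two shape ratios); the structure threshold `φ` is gray-level dependent and,
when not given, is set per volume and scale to half the maximum Frobenius
norm — a choice that adapts to contrast without a free parameter.

## Aorta localization and seeding

The ascending aorta is the largest, brightest, near-circular structure on
axial slices, which makes it the anchor for fully automatic seeding. Two
detectors share one contract (per-slice binary masks):

- **Learned**: a small convolutional encoder–decoder (depth 3, base 8
  channels, single 3×3 convolution + ReLU per level, 2×2 average pooling,
  nearest-neighbor upsampling with skip concatenation, 1×1 sigmoid head)
  trained with Adam (lr 10⁻², batch 8, 30 epochs) under the smoothed Dice
  loss

  `DiceLoss = 1 − (2 Σ lab·pre + smooth) / (Σ pre + Σ lab + smooth)`

  with `smooth = 1` keeping the ratio defined when both masks are empty.
  The network and its backpropagation are implemented directly in NumPy;
  at these sizes (64×64 slices) training completes in about a minute on one
  CPU core and is bit-reproducible from a single integer seed.
  Probabilities are thresholded at 0.5.
- **Fallback** (deterministic, no training): Otsu-threshold the slice, label
  connected components, return the largest whose isoperimetric circularity
  `4πA/P² ≥ 0.7`. Note a filled square scores π/4 ≈ 0.785, so the 0.7 cut
  rejects elongated or ragged regions, not every polygon.

The coronary **seed** is the voxel outside the stacked aorta mask, within
`search_radius` voxels (default 5) of its surface, with maximal fused
vesselness; ties break toward the lexicographically smallest (z, y, x).
Because vesselness along the coronary root rises with distance from the
aorta (the large neighbor suppresses the tube response), the argmax sits
near the outer edge of the search band — on the vessel, a few voxels distal
to the anatomical junction, which is exactly where growth should start.

## Region growing

Growth is breadth-first from the seed. A candidate voxel is accepted iff

```
vesselness ≥ τ_v   and   |enhanced − μ_seed| ≤ τ_i
```

where `μ_seed` is the mean enhanced intensity over the seed and its
immediately qualifying neighbors, **frozen after initialization**. Freezing
makes the acceptance test static, so the grown set equals the connected
component of the pass-mask containing the seed and is provably independent
of frontier order (a running-mean variant is order-dependent and was
rejected). Rejected voxels are marked and never re-tested; every voxel is
evaluated at most once, so termination is immediate by counting. The
frontier is a FIFO queue, fixed only to make traversal logs reproducible.
Defaults: `τ_v = 0.05`, `τ_i = 60` enhanced-intensity units, 26-connectivity,
voxel cap = grid size (`max_voxels` terminates growth only when a further
candidate qualifies beyond the cap).

The **traditional baseline** is the identical algorithm with the vesselness
gate removed — the classic intensity-only seeded growth that requires a
manual seed and threshold and leaks through any intensity bridge.

The full pipeline excludes the detected aorta (dilated by one voxel, which
also covers its surface response) from the growth domain: the aorta is the
seeding anchor, not the segmentation target, and without the exclusion
growth would trace the aorta wall.

## Evaluation metrics

- **Pixel accuracy** (per-slice, for the aorta segmenter): mean over test
  samples of (correctly predicted positive pixels)/(positive label pixels);
  samples with empty labels are excluded from the mean and counted
  separately rather than scored 0/0.
- **Average voxel error** (per-volume, for the grown mask): over the union
  C of predicted and reference masks, the mean of |o_i − O_i| where o_i is
  the volume HU under the predicted mask (else 0) and O_i under the
  reference (else 0). The "masked-HU difference" reading is this package's
  concretization — each disagreement costs the full local HU magnitude, so
  the number is in HU/voxel and drops to 0 only at exact agreement.
- **Diagnostic metrics** (per-patient): sensitivity, specificity, PPV, NPV
  and accuracy from a 2×2 table against a reference standard, reported as
  percentages rounded half-up to two decimals; a metric whose denominator is
  zero is returned as undefined (None) rather than raising. From the counts
  tn = 26, fp = 4 the computed specificity is 86.67% (26/30).
- **Image-quality scores** (0–3 rubric) exist as a labelled enum only; the
  scoring act is a human read and is not computed.

## Synthetic phantoms

No clinical volumes ship with the package; every stage is exercised on
deterministic phantoms:

- `generate_phantom`: a vertical-cylinder aorta (radius 8 voxels, 450 HU), a
  coronary tree (main branch of radius 2.5 voxels leaving the aorta surface
  plus two children at ±35°, 400 HU) on a 64³ grid of 0.5 mm voxels,
  soft-tissue background (50 HU), optional 1-voxel 800 HU stent ring with
  the lumen narrowed by a stenosis fraction, and additive Gaussian noise
  (default sd 10 HU). HU plateaus are exact before noise, so thresholding
  the noiseless volume recovers the ground-truth masks exactly. The HU
  levels sit inside the 0–600 HU working window so windowing is
  non-degenerate; noise sd 10 HU approximates the lumen noise of a modern
  coronary CTA protocol.
- `straight_tube_phantom` and `leakage_phantom`: minimal geometries for the
  growth stage; the leakage phantom attaches an equal-intensity sphere to
  the tube — the configuration in which intensity-only growth floods the
  sphere.

What the phantoms do **not** emulate: anatomy (curved vessels, myocardium,
bone), cardiac motion, beam hardening or metal artifacts, partial-volume
blur, or anisotropic acquisition. Passing phantom tests therefore
demonstrates algorithmic correctness — the formulas, gates and contracts
behave as specified — not clinical performance. In particular the phantoms'
hard voxel edges produce Frangi-type edge responses on large-structure
surfaces (the known edge-response behavior of Hessian filters); the
leakage demonstration therefore reports both the error ordering at the
default gate and the containment achieved at a stricter gate (τ_v = 0.2),
under which growth stays out of the sphere beyond the one-voxel contact
layer that is genuinely ambiguous at voxel resolution.

## Problem sizes and numerical choices

Phantom studies use 48³–64³ grids, a 10-phantom leakage suite, and an
80-slice training set (64 train / 16 held out) — sizes at which the full
acceptance run completes in about a minute on one CPU core while leaving
every contrast (improved vs. traditional, fused vs. single-scale) far from
marginal. Other fixed choices: eigen-decomposition via symmetric `eigh`
with stable |·| re-ordering; discrete Gaussian derivative kernels truncated
at 4 sd (a constant volume then yields Hessian residuals of order 10⁻⁴,
the tolerance tests use); probabilities thresholded at 0.5; the Dice
`smooth` constant 1.0; seed ties broken lexicographically; all randomness
routed through `numpy.random.default_rng` seeds carried in the configs.

## Known limitations

- Vesselness edge responses on large bright structures are suppressed only
  via the aorta exclusion and the τ_v gate, not by a dedicated edge filter.
- The region-growing intensity gate uses a single frozen statistic; slow
  intensity drift along a long vessel would eventually exceed τ_i.
- Voxel spacing participates in I/O metadata but derivative kernels operate
  in voxel units (per-axis scaling only), so strongly anisotropic volumes
  should be resampled first.
- The learned aorta segmenter is sized for phantom slices; clinical use
  would need retraining on real annotated slices.
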