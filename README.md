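# corogrow

Vesselness-gated seeded region growing for coronary CT angiography (CTA),
with automatic aorta-based seed localization and a synthetic phantom bench
for end-to-end validation.

## The problem

Coronary arteries in contrast-enhanced cardiac CT are thin (≈1–4 mm), bright
(≈300–450 HU) tubes embedded among other bright structures — the aorta, the
cardiac chambers, calcifications — often separated from them by only a few
partial-volume voxels. Classic seeded region growing, which accepts any
connected voxel of similar intensity, is fast and simple but **leaks**: the
grown region floods through any intensity bridge into a chamber or a vein,
and it needs a manually placed seed. This package implements an improved
growth procedure in which each candidate voxel must additionally look
*tubular* according to a multiscale Hessian vesselness filter, and the seed
is placed automatically at the aorta–coronary junction.

## Method

Four stages (see [docs/methods.md](docs/methods.md) for derivations and
parameter rationale):

1. **Windowing.** HU values are mapped to an enhanced display range with a
   window level/width transform (`wl = 300`, `ww = 600` HU):
   `y = 128 + 256 (x − wl)/ww` on the linear branch, clamped to [0, 255].

2. **Multiscale vesselness.** At each Gaussian scale α the Hessian
   eigenvalues `|β₁| ≤ |β₂| ≤ |β₃|` define `R_A = |β₂|/|β₃|`,
   `R_B = |β₁|/√|β₂β₃|` and the Frobenius norm `S`; the score

   `V = (1 − e^{−R_A²/2ε²}) · e^{−R_B²/2ϕ²} · (1 − e^{−S²/2φ²})`

   (zero where β₂ > 0 or β₃ > 0) is near 1 inside bright tubes and near 0
   for plates, blobs and noise. Scales are fused by voxelwise maximum with
   γ-normalization (`×α²`), so the best-responding scale tracks the vessel
   radius.

3. **Aorta seed.** A small convolutional encoder–decoder (pure NumPy,
   trained under the smoothed Dice loss) — or a deterministic
   Otsu + circularity fallback — segments the aorta on axial slices; the
   coronary seed is the highest-vesselness voxel just outside the aorta
   surface.

4. **Growing.** Breadth-first growth from the seed accepts a voxel iff
   `V ≥ τ_v` **and** `|enhanced − μ_seed| ≤ τ_i`, with μ_seed frozen at
   initialization (defaults τ_v = 0.05, τ_i = 60, 26-connectivity). The
   result is provably order-independent. The traditional intensity-only
   baseline is the same algorithm with τ_v = 0.

Evaluation utilities compute per-slice pixel accuracy, per-volume average
voxel error (HU-weighted disagreement over the union of masks), and 2×2
diagnostic metrics (sensitivity, specificity, PPV, NPV, accuracy).

No clinical data ships with the package; everything is validated on
deterministic synthetic phantoms (cylindrical aorta + branching coronary
tree + noise) whose ground-truth masks are exact by construction.

## Worked example

```python
from corogrow import PhantomConfig, PipelineConfig, generate_phantom, run_pipeline
from corogrow.io import write_volume

sample = generate_phantom(PhantomConfig(rng_seed=42))   # 64³, noisy
write_volume(sample.volume, "phantom.nii.gz", sample.config.spacing)

manifest = run_pipeline("phantom.nii.gz", PipelineConfig(output_dir="out"),
                        reference_mask=sample.vessel_mask)
out = manifest["outputs"]
print(out["seed"], out["n_accepted"], out["metrics"])
```

prints (exactly, for this seed):

```
[30, 32, 33] 1010 {'voxel_error': 75.04…, 'dice': 0.9056…, 'n_voxels': 1072}
```

The pipeline windowed the volume, computed fused vesselness, located the
aorta with the fallback detector, seeded at voxel (30, 32, 33) on the
coronary root, grew 1010 voxels, and scored Dice 0.906 against the known
coronary mask. All artifacts (enhanced volume, vesselness map, grown mask,
`manifest.json`) land in `out/`.

The same run from the shell:

```bash
corogrow phantom --seed 42 ph          # ph_volume / ph_vessel / ph_aorta .nii.gz + truth JSON
corogrow run ph_volume.nii.gz --out-dir out
corogrow evaluate out/mask.nii.gz ph_vessel.nii.gz --volume ph_volume.nii.gz
# -> {"voxel_error": {"error": 75.04…, "n_voxels": 1072}}
```

Individual stages are also exposed (`corogrow window | vesselness | seed |
grow`), each reading/writing NIfTI.

On a phantom with an equal-intensity blob welded to the vessel, the
traditional baseline floods the blob while the gated growth stays on the
tube: over ten random phantoms the mean voxel error is ≈245 HU/voxel
(improved) vs ≈317 HU/voxel (traditional) at identical seeds and intensity
tolerance.

## Layout

```
src/corogrow/
  phantom.py     synthetic vascular phantoms + training-pair generator
  windowing.py   HU window/level transform
  vesselness.py  Hessian, eigen-decomposition, single/multiscale vesselness
  nn.py          NumPy conv net primitives (forward + backward, Adam)
  aorta.py       Dice loss, segmenter training, fallback detector, locate_seed
  growing.py     gated region growing + traditional baseline
  metrics.py     pixel accuracy, average voxel error, diagnostic metrics
  io.py          NIfTI volume/mask I/O
  pipeline.py    staged end-to-end pipeline with manifest
  cli.py         `corogrow` command-line interface
docs/methods.md  methods note (models, parameters, phantom scope, limitations)
tests/           pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py  seeded reproduction script
```
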