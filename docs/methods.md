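# Methods

## Model

The package segments the aorta in CT volumes with a single shared 2-D
segmenter threaded recurrently through 2.5D *slice blocks*.  A block is
`n` consecutive slices of one case; stride-1 blocks are taken over a case
of `S` slices, so there are `S − n + 1` blocks and the slice indices
`n−1 … S−1` each appear exactly once as a block's target.  Within a
block, slice 0 is segmented from its raw (windowed) intensities; for each
subsequent slice the previous slice's foreground-probability map is
converted into a hard-attention *enhancement map* and multiplied into the
slice before segmentation.  A block therefore performs exactly `n − 1`
enhancement steps, and the last slice's prediction is the block's output.

The enhancement map is piecewise constant on a grid of `ks × ks` kernels:
a kernel whose mean predicted foreground probability strictly exceeds a
threshold `eps` takes the value `EF`; every other kernel takes 1.0.  The
kernel granularity is the mechanism that absorbs inter-slice anatomical
drift — the enhanced region is a kernel-resolution dilation of the
previous prediction.  The scheme assumes what makes it work anatomically:
the aorta's position and cross-section change only slightly between
adjacent slices, so "where it just was" predicts "where it is" up to a
kernel-sized margin.  When slices are far apart (large voxel depth) that
assumption weakens, which is what the kernel-size × voxel-depth ablation
grid probes.

No parameters are introduced by the enhancement: `EF`, `eps` and `ks`
are fixed scalars, and the map construction is a non-differentiable
threshold.  Consequently the previous prediction is treated as a constant
during training (no gradient flows through the map), and training reduces
to backpropagation through the current slice's forward pass only.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n` (block size) | slices per 2.5D block | 4 | main-experiment setting; 2 and 3 supported for the block-size ablation |
| `ks` (kernel size) | enhancement kernel side, px | 16 | main setting at 512×512 / 0.625 mm; 8 and 32 for the ablation |
| `EF` (factor) | multiplier inside enhanced kernels | 1.1 (Level 1) / 1.4 (Level 2) | the validated per-level factors; `default_factor(level)` |
| `eps` | kernel-mean threshold (strict `>`) | 0.5 | majority evidence within a kernel; the source protocol does not report its value, so this is the package's own choice, configurable |
| window | HU → [0,1] affine clip | (−100, 600) HU | spans soft tissue through strongly enhanced blood, so multiplication brightens rather than inverts; intensity preprocessing is not specified upstream |
| `B` (channel width) | channels after the first convolution | 64 (tests use 8) | 64 matches the complexity analysis; 8 keeps CPU tests fast |
| training | batch 4, lr 1e-6, 200 epochs, Adam | — | the study-scale protocol, kept as `TrainConfig` defaults |
| binarization | evaluation threshold on probabilities | 0.5 | two-class argmax; ties (exactly 0.5) fall to background |

`eps ≥ 1` is accepted and documented as an off-switch: a probability
kernel mean can never strictly exceed 1, so the step reduces to the
identity.

## Level classification

Cases are classified by the mean HU over all ground-truth aorta voxels:
strictly above 250 HU → Level 1 (well contrasted); inside the closed
interval [100, 250] HU → Level 2 (poorly contrasted); below 100 HU →
excluded.  The boundary value 250 belongs to Level 2, reading "over 250"
as strict.  The statistic (mean) is the least surprising reading of
"CT values at the aorta locations" and is configurable (`statistic=
"median"`); which statistic the source protocol used is not stated.

## Numerical and design choices

- **Boundary kernels.**  If `H` or `W` is not divisible by `ks`, the
  prediction is zero-padded bottom/right to the next multiple and the map
  cropped back.  Zero-padding biases boundary kernels toward
  non-enhancement (conservative).  The brute-force oracle in the tests
  uses the same convention (kernel sums divided by `ks²`).
- **Soft vs. hard map input.**  Kernel means are computed on the soft
  probability map by default; `binarize_first=True` thresholds at 0.5
  first.  Upstream practice is ambiguous on this point.
- **No clipping after multiplication.**  Enhanced intensities may exceed
  1.0 (up to `EF`); clipping would destroy exactly the contrast the step
  adds, so the segmenter contract requires accepting unbounded
  non-negative inputs.
- **Ties.**  Kernel mean exactly equal to `eps` → not enhanced (strict
  "exceeds").  Probability exactly 0.5 at evaluation → background.
- **Loss.**  Mean per-pixel two-class cross-entropy on the target slice;
  `supervise_intermediate=True` adds equally weighted terms for slices
  `1 … n−2` (slice 0 is never enhanced and never supervised).  The
  upstream loss and supervision scheme are unreported; plain target-slice
  cross-entropy is the minimal choice.
- **Short cases.**  Cases with fewer than `n` slices are skipped with a
  logged warning, not padded.
- **Averaging.**  Micro (pooled-count) DSC/IoU is the headline number;
  per-slice macro means are reported alongside.  Empty-vs-empty masks
  score 1.0 (agreement on absence); empty-vs-non-empty score 0.0 — the
  raw formulas are 0/0 there.
- **Reference segmenter.**  Canonical 4-level U-Net (two 3×3 conv + ReLU
  per level, 2× max-pool, nearest upsampling + channel-halving conv, skip
  concatenation, 1×1 head to 2 classes, softmax), implemented in NumPy
  with hand-derived backpropagation and Adam; gradients are verified
  against central finite differences in the test suite.  Default compute
  dtype is float32; float64 is used for the gradient checks.  Transformer
  backbones are deliberately not reimplemented — any model satisfying the
  segmenter contract (shape-preserving, probabilities in [0,1], exact
  parameter count) can be registered and plugged in.  For the record,
  the upstream transformer settings were: TransUNet 12 layers, hidden
  size 768, MLP ratio 4, 12 heads; Swin-UNet window size 16 at 512×512.
- **Determinism.**  All randomness flows through explicit integer seeds
  (phantom specs, weight init, epoch shuffling); repeated runs reproduce
  volumes bitwise and loss traces bitwise on CPU.
- **FLOPs accounting.**  Analytic, convolutions only, one
  multiply–accumulate = 2 FLOPs.  Block-mode inference quotes `m ×` the
  single-slice figure as the cost per target slice; the enhancement's
  `O(N)` term (≈ `2N + 2N/ks²` FLOPs per step) is reported separately
  and excluded from the headline figure.

## The phantom generator

`generate_phantom` emulates the structural properties the method
exploits, not CT physics.  Vessels are filled ellipses with integer-pixel
centres performing a bounded random walk (default drift ≤ 2 px/slice at
64×64 — the inter-slice aortic displacement is not quantified upstream,
so this is a modelling choice) and smoothly random-walking radii, over a
uniform soft-tissue background (40 HU) with optional lung-like low-HU
ovals (−700 HU).  A per-case foreground HU value is drawn safely inside
the requested level interval (Level 1: 290–450 HU, Level 2: 120–230 HU),
so with `noise_sd=0` the case-level foreground mean is exactly in range;
additive zero-mean Gaussian noise (default sd 10 HU) is applied last.
Vessels can split into two lobes and merge back (`branch_probability`),
mimicking branching anatomy at the crudest useful level.  Default
geometry is 64×64×8 for fast CPU runs; 512×512 matches the clinical
in-plane resolution.

What the phantoms do **not** have: anatomical shape (arch, branches with
real topology), partial-volume effects, beam hardening, scanner noise
texture, neighbouring organs of similar HU, or inter-patient intensity
variability.  Passing the phantom tests therefore shows the pipeline is
implemented correctly and that enhancement helps when its structural
premise holds; it does not certify clinical accuracy.

## Desk-scale experiment sizes

The published accuracy tables come from GPU training on clinical volumes
(512×512, hundreds of slices, 200–800 epochs); those magnitudes are out
of reach for a CPU test suite and are not reproduced.  The package's own
efficacy study (`ascseg.experiments`) uses: 6 training + 2 held-out
Level-2 phantoms of 8 slices at 64×64, reference segmenter at `B = 8`,
`n = 4`, `ks = 16`, `EF = 1.4`, `eps = 0.5`, 20 epochs at learning rate
3e-3 (Adam).  The study-scale rate of 1e-6 is kept as the `TrainConfig`
default but is far too small to leave initialization within 20 epochs;
3e-3 is the package's desk-scale choice.  The comparison is paired and
directional: for each seed, baseline and enhancement-wrapped models share
initialization, data and shuffling, and the claim checked is only that
enhancement matches or beats the baseline's held-out mean DSC in most
seeds.

## Known limitations

- The reference segmenter is small and NumPy-bound; it demonstrates the
  pipeline, not state-of-the-art accuracy, and its parameter count is its
  own (the upstream U-Net variant reporting 34.53 M parameters is not
  specified at the level of detail needed to match it).
- Enhancement factors are global scalars per contrast level; intensity
  variability along the aorta means multiplication does not always land
  intensities in an optimal range.  Learnable or spatially adaptive
  factors are explicitly out of scope.
- The published benchmark tables embedded in `ascseg.report` contain two
  internal inconsistencies between their summary and detail variants
  (UNet+ASC IoU 67.99 vs 68.23; Swin-UNet+ASC DSC 60.76 vs 61.66); the
  improvement arithmetic uses the main (per-level) tables and does not
  attempt to resolve the discrepancy.
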