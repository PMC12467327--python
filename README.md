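# ascseg — slice-recurrent aorta segmentation for poorly contrasted CT

2-D segmentation networks localize the aorta well on optimally
contrast-enhanced CT, but their accuracy collapses when contrast agent is
reduced or absent (aortic blood at 100–250 HU instead of > 250 HU).
`ascseg` implements an *automatic spatial contrast* (ASC) scheme that
exploits a physiological fact: between adjacent CT slices the aorta moves
only slightly and keeps a similar cross-section.  The previous slice's
prediction is therefore a cheap, anatomy-aware prior for where to boost
contrast in the current slice.

## The method

Let `x` be the current (intensity-normalized) slice and `V_p` the
foreground-probability map predicted for the previous slice.  `V_p` is
partitioned into `ks x ks` kernels, and each kernel is assigned a value

```
KV_e(h, w) = EF    if mean(V_p over the kernel) > eps
             1.0   otherwise
```

giving a piecewise-constant *enhancement map* `e_m ∈ {1.0, EF}^{H x W}`.
The slice fed to the segmenter is the element-wise product

```
x' = x ⊙ e_m ,
```

so intensities are multiplied by `EF > 1` exactly where the aorta was just
seen (plus a kernel-sized margin that absorbs the inter-slice drift) and
left untouched elsewhere — hard attention, with zero trainable
parameters.  Applied recurrently over a 2.5D block of `n` consecutive
slices (slice 0 raw, each later slice enhanced by its predecessor's
prediction, `n − 1` enhancement steps in total), one shared 2-D segmenter
gains through-plane context at essentially 2-D memory cost.  The
enhancement adds only `O(N)` work per slice against the segmenter's
`O(N B²)` — a fraction `1/B²` (1/4096 at channel width `B = 64`).

Evaluation uses the Dice similarity coefficient and IoU,
`DSC = 2TP/(2TP+FP+FN)`, `IoU = TP/(TP+FP+FN)`, pooled over evaluated
slices, plus difference maps (black/white/blue/red for TN/TP/FN/FP) and
the analytic false-positive sensitivity `∂DSC/∂FP = −2TP/(2TP+FP+FN)²`.

Everything is testable without clinical data: a seeded phantom generator
produces multi-slice volumes whose elliptical "aortic" cross-sections
drift slightly between slices, with contrast levels, branching/merging
vessels, voxel depths and noise all configurable.

## Worked example

Train the enhancement-wrapped reference segmenter on six poorly
contrasted (Level-2) phantom cases and evaluate a held-out case:

```python
from ascseg import ASCSegmentation, ASCConfig, PhantomSpec, generate_phantom
from ascseg.pipeline import TrainConfig
from ascseg.segmenter import ReferenceUNetConfig

train_cases = [generate_phantom(PhantomSpec(level=2, seed=s)) for s in range(101, 107)]
test_vol, test_mask = generate_phantom(PhantomSpec(level=2, seed=901))

model = ASCSegmentation(
    train_cases,
    block_size=4,                                   # slices per 2.5D block
    asc=ASCConfig(kernel_size=16, epsilon=0.5, factor=1.4),
    segmenter_config=ReferenceUNetConfig(channel_width=8, depth=4),
    train_config=TrainConfig(seed=0),
)
results = model.fit(epochs=20, learning_rate=3e-3)   # desk-scale settings
print(results.summary())

report = results.evaluate(test_vol, test_mask, mode="block")
print(f"held-out DSC = {report.dsc:.3f}, IoU = {report.iou:.3f}")
```

Output:

```
Slice-Recurrent Segmentation Results
====================================================
Segmenter:                  reference_unet
Trainable parameters:       540,082
Channel width (B):          8
Block size (n):             4
Enhancement:                ks=16, eps=0.5, EF=1.4
Training cases / blocks:    6 / 30
Epochs:                     20
Learning rate:              0.003
Optimizer:                  adam
Seed:                       0
First/last epoch loss:      0.368361 / 0.034909
====================================================
held-out DSC = 0.693, IoU = 0.530
```

The summary confirms the enhancement wrapper added no parameters (the
count is the bare segmenter's), the loss trace shows convergence, and the
held-out scores are micro-averaged over the target slices of all stride-1
blocks.  `mode="carry"` instead carries one prediction sequentially
through the whole case.

A command-line layer wraps the same library:

```
asc-seg simulate --config phantoms.yaml --out data/
asc-seg train    --config run.yaml --weights-out w.npz
asc-seg infer    --config run.yaml --case data/case-000.nrrd --weights w.npz
asc-seg eval     --pred predictions/ --gt data/
asc-seg ablate   --grid grid.yaml
```

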