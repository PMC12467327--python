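"""Slice-recurrent training and inference loops.

One shared 2-D segmenter is threaded through a block of n consecutive
slices: slice 0 is segmented from its raw intensities; for each later
slice the previous slice's prediction is turned into an enhancement map
that multiplies the current slice before segmentation.  A block of n
slices therefore executes exactly n - 1 enhancement steps, and the last
slice's prediction is the block's output.  The previous prediction is a
constant with respect to gradients: the hard threshold in the map is not
differentiable, so training backpropagates only through the current
slice's forward pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .asc import ASCConfig, build_enhancement_map, apply_enhancement
from .blocks import SliceBlock, WindowSpec, make_blocks, shuffle_blocks
from .io_formats import CTVolume, MaskVolume
from .metrics import MetricsResult, confusion_counts, dsc_from_counts, iou_from_counts
from .segmenter import Segmenter, softmax_cross_entropy, Adam, _softmax

__all__ = [
    "TrainConfig",
    "BlockPrediction",
    "InferenceResult",
    "EvaluationReport",
    "infer_block",
    "infer_volume",
    "train",
    "evaluate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the main-experiment protocol
    (batch 4, learning rate 1e-6, 200 epochs, Adam)."""

    batch_size: int = 4
    learning_rate: float = 1e-6
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    supervise_intermediate: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


def _check_probability(prob: np.ndarray, shape: tuple) -> np.ndarray:
    prob = np.asarray(prob)
    if prob.shape != shape:
        raise ValueError(
            f"segmenter contract violation: output shape {prob.shape} != input {shape}")
    if not np.isfinite(prob).all() or prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("segmenter contract violation: output not a probability map")
    return prob


@dataclass
class BlockPrediction:
    """Prediction for a block's target slice plus recurrence bookkeeping."""

    probability: np.ndarray
    enhancement_steps: int
    intermediate: list = field(default_factory=list)


def infer_block(block: SliceBlock, segmenter: Segmenter, cfg: ASCConfig,
                keep_intermediate: bool = False) -> BlockPrediction:
    """Run the recurrent pass over one block and return the target prediction.

    Executes exactly ``block.n - 1`` enhancement steps, exposed on the
    returned object.
    """
    prob = _check_probability(segmenter.predict(block.slices[0]),
                              block.slices[0].shape)
    steps = 0
    intermediate = [prob] if keep_intermediate else []
    for k in range(1, block.n):
        e_m = build_enhancement_map(prob, cfg)
        x = apply_enhancement(block.slices[k], e_m)
        steps += 1
        prob = _check_probability(segmenter.predict(x), x.shape)
        if keep_intermediate and k < block.n - 1:
            intermediate.append(prob)
    return BlockPrediction(prob, steps, intermediate)


@dataclass
class InferenceResult:
    """Per-target-slice probability maps with provenance."""

    case_id: str
    mode: str
    slice_indices: list[int]
    probabilities: list[np.ndarray]
    enhancement_steps: int

    def masks(self, threshold: float = 0.5) -> list[np.ndarray]:
        """Binary masks: foreground where probability exceeds the threshold
        (the two-class argmax at 0.5)."""
        return [(p > threshold).astype(np.uint8) for p in self.probabilities]


def infer_volume(volume: CTVolume | np.ndarray, segmenter: Segmenter,
                 cfg: ASCConfig, mode: str = "block", n: int = 4,
                 window: WindowSpec | None = WindowSpec()) -> InferenceResult:
    """Predict a whole case.

    ``block`` mode runs the recurrent pass on every stride-1 block of ``n``
    slices, yielding predictions for slices n-1 .. S-1 (the evaluation
    protocol).  ``carry`` mode makes one sequential pass: slice 0 raw,
    every later slice enhanced by the immediately preceding prediction,
    yielding S predictions and S-1 enhancement steps.
    """
    if isinstance(volume, CTVolume):
        case_id = volume.case_id
        data = volume.slices
    else:
        case_id, data = "", np.asarray(volume)
    from .blocks import normalize_hu

    norm = normalize_hu(data, window) if window is not None else data
    S = norm.shape[0]
    if mode == "block":
        if S < n:
            raise ValueError(f"case {case_id or '<anonymous>'}: {S} slices < block size {n}")
        indices, probs, steps = [], [], 0
        for start in range(S - n + 1):
            block = SliceBlock(norm[start:start + n], None, start, case_id)
            bp = infer_block(block, segmenter, cfg)
            indices.append(start + n - 1)
            probs.append(bp.probability)
            steps += bp.enhancement_steps
        return InferenceResult(case_id, "block", indices, probs, steps)
    if mode == "carry":
        if S < 2:
            raise ValueError(f"case {case_id or '<anonymous>'}: need >= 2 slices for carry mode")
        prob = _check_probability(segmenter.predict(norm[0]), norm[0].shape)
        indices, probs, steps = [0], [prob], 0
        for s in range(1, S):
            e_m = build_enhancement_map(prob, cfg)
            x = apply_enhancement(norm[s], e_m)
            steps += 1
            prob = _check_probability(segmenter.predict(x), x.shape)
            indices.append(s)
            probs.append(prob)
        return InferenceResult(case_id, "carry", indices, probs, steps)
    raise ValueError(f"unknown mode {mode!r}; expected 'block' or 'carry'")


# ---------------------------------------------------------------------------
# training

def _batch_enhance(prev_probs: np.ndarray, raw: np.ndarray, cfg: ASCConfig) -> np.ndarray:
    out = np.empty_like(raw, dtype=np.float64)
    for b in range(raw.shape[0]):
        out[b] = apply_enhancement(raw[b], build_enhancement_map(prev_probs[b], cfg))
    return out


def train(blocks: Sequence[SliceBlock], segmenter: Segmenter,
          asc_cfg: ASCConfig | None, train_cfg: TrainConfig = TrainConfig()):
    """Train the shared segmenter over a stream of supervised blocks.

    With an :class:`ASCConfig` the forward pass per block mirrors
    :func:`infer_block`; without one (baseline), the segmenter is trained
    on each block's raw target slice.  The loss is mean per-pixel
    cross-entropy on the target slice, plus equally weighted terms for
    slices 1 .. n-2 when ``supervise_intermediate`` is set.  Previous-slice
    predictions enter the loss only as constants.  Returns the segmenter
    and the per-epoch mean loss trace; a fixed seed reproduces the trace
    bitwise on CPU.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("empty block stream")
    if any(b.masks is None for b in blocks):
        raise ValueError("training blocks need ground-truth masks")
    n = blocks[0].n
    opt = Adam(segmenter.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    trace: list[float] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(blocks))
        epoch_losses = []
        for i0 in range(0, len(blocks), train_cfg.batch_size):
            batch = [blocks[j] for j in order[i0:i0 + train_cfg.batch_size]]
            x = np.stack([b.slices for b in batch]).astype(np.float64)   # (N, n, H, W)
            y = np.stack([b.masks for b in batch]).astype(np.int64)
            segmenter.zero_grad()
            loss = _block_forward_backward(segmenter, x, y, asc_cfg, train_cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step()
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return segmenter, trace


def _block_forward_backward(segmenter, x, y, asc_cfg, train_cfg) -> float:
    """One batched block pass: returns the (scalar) supervised loss and
    leaves accumulated gradients on the segmenter."""
    n = x.shape[1]
    if asc_cfg is None and not train_cfg.supervise_intermediate:
        logits = segmenter.forward_logits(x[:, -1], train=True)
        loss, dlogits = softmax_cross_entropy(logits, y[:, -1])
        segmenter.backward(dlogits)
        return loss
    supervised = {n - 1}
    if train_cfg.supervise_intermediate:
        supervised |= set(range(1, n - 1))
    weight = 1.0 / len(supervised)
    prev = segmenter.predict(x[:, 0])
    total = 0.0
    for k in range(1, n):
        xk = _batch_enhance(prev, x[:, k], asc_cfg) if asc_cfg is not None else x[:, k]
        if k in supervised:
            logits = segmenter.forward_logits(xk, train=True)
            loss_k, dlogits = softmax_cross_entropy(logits, y[:, k])
            segmenter.backward(dlogits * weight)
            total += weight * loss_k
            prev = _softmax(logits)[:, 1]
        else:
            prev = segmenter.predict(xk)
    return total


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """Micro (pooled-count) metrics as headline, per-slice macro secondary."""

    micro: MetricsResult
    macro_dsc: float
    macro_iou: float
    per_slice: list[MetricsResult]

    @property
    def dsc(self) -> float:
        return self.micro.dsc

    @property
    def iou(self) -> float:
        return self.micro.iou

    def as_dict(self) -> dict:
        d = self.micro.as_dict()
        d["macro_DSC"] = self.macro_dsc
        d["macro_IoU"] = self.macro_iou
        return d


def evaluate(result: InferenceResult, masks: MaskVolume | np.ndarray,
             threshold: float = 0.5) -> EvaluationReport:
    """Compare predictions against ground truth at their recorded slice
    indices, pooling TP/FP/FN/TN over all evaluated slices."""
    g = masks.masks if isinstance(masks, MaskVolume) else np.asarray(masks)
    if max(result.slice_indices, default=-1) >= g.shape[0]:
        raise ValueError("provenance mismatch: prediction index beyond mask volume")
    tp = fp = fn = tn = 0
    per_slice = []
    for idx, pred in zip(result.slice_indices, result.masks(threshold)):
        c = confusion_counts(pred, g[idx])
        per_slice.append(MetricsResult(*c))
        tp += c[0]; fp += c[1]; fn += c[2]; tn += c[3]
    macro_dsc = float(np.mean([m.dsc for m in per_slice]))
    macro_iou = float(np.mean([m.iou for m in per_slice]))
    return EvaluationReport(MetricsResult(tp, fp, fn, tn), macro_dsc, macro_iou, per_slice)
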