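"""Model/Results interface over the slice-recurrent pipeline.

:class:`ASCSegmentation` is built from supervised cases (CT volumes with
aorta masks) and configuration; :meth:`ASCSegmentation.fit` trains the
shared 2-D segmenter through the recurrent enhancement loop and returns an
:class:`ASCSegmentationResults` carrying the trained weights, the loss
trace and evaluation helpers, with a ``summary()`` table in the style of
statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .asc import ASCConfig
from .blocks import WindowSpec, blocks_from_cases
from .io_formats import CTVolume, MaskVolume, CaseManifest, read_volume, read_mask
from .pipeline import (TrainConfig, InferenceResult, EvaluationReport,
                       infer_volume, train, evaluate)
from .segmenter import (Segmenter, ReferenceUNetConfig, get_segmenter_builder,
                        param_count)

__all__ = ["ASCSegmentation", "ASCSegmentationResults"]


class ASCSegmentation:
    """Slice-recurrent aorta segmentation model.

    Parameters
    ----------
    cases : sequence of (CTVolume, MaskVolume)
        Supervised training cases.
    block_size : int
        Slices per 2.5D block (n >= 2); the last slice of each block is
        the supervised target.
    asc : ASCConfig or None
        Enhancement configuration.  ``None`` trains the identical
        segmenter without enhancement (the 2-D baseline).
    segmenter : str
        Registry name of the 2-D sub-model (default ``"reference_unet"``).
    """

    def __init__(self, cases: Sequence[tuple[CTVolume, MaskVolume]],
                 block_size: int = 4,
                 window: WindowSpec | None = WindowSpec(),
                 asc: ASCConfig | None = ASCConfig(),
                 segmenter: str = "reference_unet",
                 segmenter_config: ReferenceUNetConfig | None = None,
                 train_config: TrainConfig = TrainConfig()):
        self.cases = list(cases)
        self.block_size = block_size
        self.window = window
        self.asc = asc
        self.segmenter_name = segmenter
        self.segmenter_config = segmenter_config or ReferenceUNetConfig()
        self.train_config = train_config
        self.blocks = blocks_from_cases(self.cases, block_size, window)
        if not self.blocks:
            raise ValueError("no usable training blocks (all cases shorter than block_size?)")

    @classmethod
    def from_manifest(cls, manifest: CaseManifest | str | Path,
                      levels: Sequence[int] = (1, 2), **kwargs) -> "ASCSegmentation":
        """Build the model from a case manifest CSV (image + mask paths)."""
        if not isinstance(manifest, CaseManifest):
            manifest = CaseManifest.from_csv(manifest)
        cases = []
        for entry in manifest:
            if entry["level"] not in levels:
                continue
            vol = read_volume(entry["path"])
            vol.case_id = entry["case_id"]
            cases.append((vol, read_mask(entry["mask_path"])))
        return cls(cases, **kwargs)

    def build_segmenter(self, seed: int | None = None) -> Segmenter:
        builder = get_segmenter_builder(self.segmenter_name)
        return builder(self.segmenter_config,
                       seed=self.train_config.seed if seed is None else seed)

    def fit(self, epochs: int | None = None, learning_rate: float | None = None,
            seed: int | None = None) -> "ASCSegmentationResults":
        """Train the shared segmenter; optional overrides for desk-scale runs."""
        cfg = self.train_config
        if epochs is not None:
            cfg = replace(cfg, epochs=epochs)
        if learning_rate is not None:
            cfg = replace(cfg, learning_rate=learning_rate)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        segmenter = self.build_segmenter(seed=cfg.seed)
        params_before = param_count(segmenter)
        segmenter, trace = train(self.blocks, segmenter, self.asc, cfg)
        assert param_count(segmenter) == params_before
        return ASCSegmentationResults(self, segmenter, trace, cfg)


@dataclass
class ASCSegmentationResults:
    """Fitted slice-recurrent segmentation model."""

    model: ASCSegmentation
    segmenter: Segmenter
    loss_trace: list[float]
    train_config: TrainConfig

    @property
    def parameter_count(self) -> int:
        return param_count(self.segmenter)

    def predict(self, volume: CTVolume | np.ndarray, mode: str = "block") -> InferenceResult:
        """Segment a case; with enhancement if the model was ASC-configured."""
        if self.model.asc is not None:
            return infer_volume(volume, self.segmenter, self.model.asc,
                                mode=mode, n=self.model.block_size,
                                window=self.model.window)
        return self._predict_plain(volume)

    def _predict_plain(self, volume) -> InferenceResult:
        from .blocks import normalize_hu
        from .pipeline import _check_probability

        if isinstance(volume, CTVolume):
            case_id, data = volume.case_id, volume.slices
        else:
            case_id, data = "", np.asarray(volume)
        norm = normalize_hu(data, self.model.window) if self.model.window is not None else data
        n = self.model.block_size
        indices = list(range(n - 1, norm.shape[0]))
        probs = [_check_probability(self.segmenter.predict(norm[s]), norm[s].shape)
                 for s in indices]
        return InferenceResult(case_id, "plain", indices, probs, 0)

    def evaluate(self, volume: CTVolume | np.ndarray, masks: MaskVolume | np.ndarray,
                 mode: str = "block", threshold: float = 0.5) -> EvaluationReport:
        return evaluate(self.predict(volume, mode=mode), masks, threshold)

    def save_weights(self, path) -> None:
        self.segmenter.save_weights(path)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        asc = m.asc
        lines = [
            "Slice-Recurrent Segmentation Results",
            "=" * 52,
            f"{'Segmenter:':<28}{m.segmenter_name}",
            f"{'Trainable parameters:':<28}{self.parameter_count:,}",
            f"{'Channel width (B):':<28}{m.segmenter_config.channel_width}",
            f"{'Block size (n):':<28}{m.block_size}",
            f"{'Enhancement:':<28}"
            + ("off (baseline)" if asc is None else
               f"ks={asc.kernel_size}, eps={asc.epsilon}, EF={asc.factor}"),
            f"{'Training cases / blocks:':<28}{len(m.cases)} / {len(m.blocks)}",
            f"{'Epochs:':<28}{self.train_config.epochs}",
            f"{'Learning rate:':<28}{self.train_config.learning_rate:g}",
            f"{'Optimizer:':<28}{self.train_config.optimizer}",
            f"{'Seed:':<28}{self.train_config.seed}",
            f"{'First/last epoch loss:':<28}"
            f"{self.loss_trace[0]:.6f} / {self.loss_trace[-1]:.6f}",
            "=" * 52,
        ]
        return "\n".join(lines)
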