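"""Desk-scale phantom experiments.

The study-scale results (clinical volumes, GPU-budget training) are not
reproducible on a laptop CPU; this module defines the package's own
small-scale counterpart: Level-2 (poorly contrasted) phantoms at 64x64x8,
the reference segmenter at channel width 8, 4-slice blocks, a 16x16
enhancement kernel with factor 1.4, and 20 training epochs at learning
rate 1e-3-scale (the study's 1e-6 would leave the network at
initialization in so few epochs).  The comparison is directional only:
whether enhancement-wrapped training/inference matches or beats the
identically seeded baseline on held-out phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asc import ASCConfig
from .model import ASCSegmentation
from .phantom import PhantomSpec, generate_phantom
from .pipeline import TrainConfig
from .segmenter import ReferenceUNetConfig

__all__ = ["EfficacyRun", "level2_efficacy_run", "level2_efficacy_study"]

# desk-scale defaults (see docs/methods.md)
N_TRAIN_CASES = 6
N_TEST_CASES = 2
EPOCHS = 20
LEARNING_RATE = 3e-3
SEGMENTER = ReferenceUNetConfig(channel_width=8, depth=4)
ASC = ASCConfig(kernel_size=16, epsilon=0.5, factor=1.4)


@dataclass
class EfficacyRun:
    """Held-out metrics of one identically seeded baseline/ASC pair."""

    seed: int
    baseline_dsc: float
    asc_dsc: float
    baseline_iou: float
    asc_iou: float

    @property
    def asc_wins_or_ties(self) -> bool:
        return self.asc_dsc >= self.baseline_dsc


def _cases(seeds) -> list:
    return [generate_phantom(PhantomSpec(level=2, seed=s, n_slices=8)) for s in seeds]


def level2_efficacy_run(seed: int, epochs: int = EPOCHS,
                        learning_rate: float = LEARNING_RATE,
                        n_train: int = N_TRAIN_CASES,
                        n_test: int = N_TEST_CASES) -> EfficacyRun:
    """Train baseline and enhancement-wrapped models from one seed and
    evaluate both on the same held-out Level-2 phantoms."""
    train_cases = _cases(100 + seed * 20 + i for i in range(n_train))
    test_cases = _cases(900 + seed * 5 + j for j in range(n_test))
    scores = {}
    for label, asc in (("baseline", None), ("asc", ASC)):
        model = ASCSegmentation(train_cases, block_size=4, asc=asc,
                                segmenter_config=SEGMENTER,
                                train_config=TrainConfig(seed=seed))
        res = model.fit(epochs=epochs, learning_rate=learning_rate)
        reps = [res.evaluate(v, m, mode="block") for v, m in test_cases]
        scores[label] = (float(np.mean([r.dsc for r in reps])),
                         float(np.mean([r.iou for r in reps])))
    return EfficacyRun(seed, scores["baseline"][0], scores["asc"][0],
                       scores["baseline"][1], scores["asc"][1])


def level2_efficacy_study(seeds: tuple[int, ...] = (1, 2, 3),
                          **kwargs) -> list[EfficacyRun]:
    """Repeat the paired comparison over the given seeds (default 1, 2, 3)."""
    return [level2_efficacy_run(int(s), **kwargs) for s in seeds]
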