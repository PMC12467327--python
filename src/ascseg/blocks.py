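"""Intensity windowing, through-plane subsampling and 2.5D slice blocks.

A *slice block* is the unit the recurrent pipeline trains and infers on:
``n`` consecutive slices of one case, with the last slice being the
supervised/evaluated target.  Blocks are taken with stride 1, so a volume
of S slices yields ``S - n + 1`` blocks and consecutive blocks overlap in
``n - 1`` slices.  Blocks may be shuffled as units for training; their
internal slice order is never altered.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .io_formats import CTVolume, MaskVolume

__all__ = [
    "WindowSpec",
    "SliceBlock",
    "normalize_hu",
    "subsample_depth",
    "make_blocks",
    "blocks_from_cases",
    "shuffle_blocks",
    "save_block_manifest",
    "load_block_manifest",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Affine HU window: ``hu_min`` maps to 0.0 and ``hu_max`` to 1.0.

    The default (-100, 600) HU spans soft tissue through strongly
    contrast-enhanced blood, so multiplicative enhancement brightens
    rather than inverts the aorta.
    """

    hu_min: float = -100.0
    hu_max: float = 600.0

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ValueError(f"degenerate window: hu_min={self.hu_min} >= hu_max={self.hu_max}")


def normalize_hu(volume: Union[CTVolume, np.ndarray],
                 window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Map HU into [0, 1]: clip at the window edges, then rescale affinely.

    Monotone non-decreasing; values at or below ``hu_min`` become 0.0 and
    values at or above ``hu_max`` become 1.0.
    """
    arr = volume.slices if isinstance(volume, CTVolume) else np.asarray(volume)
    clipped = np.clip(arr.astype(np.float64), window.hu_min, window.hu_max)
    return ((clipped - window.hu_min) / (window.hu_max - window.hu_min)).astype(np.float32)


def subsample_depth(volume: Union[CTVolume, MaskVolume, np.ndarray],
                    stride: int):
    """Keep every ``stride``-th slice (indices 0, stride, 2*stride, ...).

    The output has ``ceil(S / stride)`` slices; for a :class:`CTVolume`
    the voxel depth is multiplied by the stride (e.g. stride 2 on a
    0.625 mm volume yields 1.25 mm).  Stride 1 is the identity.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if isinstance(volume, CTVolume):
        if stride > volume.n_slices:
            raise ValueError(f"stride {stride} exceeds slice count {volume.n_slices}")
        return CTVolume(volume.slices[::stride],
                        voxel_depth=volume.voxel_depth * stride,
                        in_plane_spacing=volume.in_plane_spacing,
                        case_id=volume.case_id)
    if isinstance(volume, MaskVolume):
        return MaskVolume(volume.masks[::stride])
    return np.asarray(volume)[::stride]


@dataclass
class SliceBlock:
    """``n`` consecutive slices of one case; the last slice is the target."""

    slices: np.ndarray          # (n, H, W), normalized intensities
    masks: np.ndarray | None    # (n, H, W) binary, or None at inference
    start_index: int
    case_id: str = ""

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 2:
            raise ValueError("a block needs >= 2 stacked 2-D slices")
        if self.masks is not None:
            self.masks = np.asarray(self.masks)
            if self.masks.shape != self.slices.shape:
                raise ValueError("mask stack must align with slice stack")

    @property
    def n(self) -> int:
        return self.slices.shape[0]

    @property
    def target_index(self) -> int:
        """Index of the supervised target slice in the source volume."""
        return self.start_index + self.n - 1

    @property
    def target_slice(self) -> np.ndarray:
        return self.slices[-1]

    @property
    def target_mask(self) -> np.ndarray | None:
        return None if self.masks is None else self.masks[-1]


def make_blocks(volume: Union[CTVolume, np.ndarray],
                masks: Union[MaskVolume, np.ndarray, None],
                n: int,
                window: WindowSpec | None = WindowSpec()) -> list[SliceBlock]:
    """Assemble all stride-1 overlapping blocks of ``n`` consecutive slices.

    Intensities are windowed to [0, 1] unless ``window`` is None (inputs
    already normalized).  A volume with fewer than ``n`` slices raises a
    ``ValueError`` naming the case and its slice count.
    """
    if n < 2:
        raise ValueError(f"block size must be >= 2, got {n}")
    if isinstance(volume, CTVolume):
        case_id = volume.case_id
        data = normalize_hu(volume, window) if window is not None else volume.slices
    else:
        case_id = ""
        data = normalize_hu(volume, window) if window is not None else np.asarray(volume)
    S = data.shape[0]
    if S < n:
        raise ValueError(
            f"case {case_id or '<anonymous>'} has only {S} slices; need at least n={n}"
        )
    marr = None
    if masks is not None:
        marr = masks.masks if isinstance(masks, MaskVolume) else np.asarray(masks)
        if marr.shape != data.shape:
            raise ValueError("mask volume must align with image volume")
    out = []
    for start in range(S - n + 1):
        out.append(SliceBlock(
            slices=data[start:start + n],
            masks=None if marr is None else marr[start:start + n],
            start_index=start, case_id=case_id))
    return out


def blocks_from_cases(cases: Sequence[tuple[CTVolume, MaskVolume]], n: int,
                      window: WindowSpec | None = WindowSpec()) -> list[SliceBlock]:
    """Pool blocks over several cases; cases shorter than ``n`` are skipped
    with a logged warning rather than padded."""
    out: list[SliceBlock] = []
    for vol, mask in cases:
        if vol.n_slices < n:
            log.warning("skipping case %s: %d slices < block size %d",
                        vol.case_id, vol.n_slices, n)
            continue
        out.extend(make_blocks(vol, mask, n, window))
    return out


def shuffle_blocks(blocks: Sequence[SliceBlock], seed: int) -> list[SliceBlock]:
    """Shuffle blocks as units with a recorded seed; internal order intact."""
    order = np.random.default_rng(seed).permutation(len(blocks))
    return [blocks[i] for i in order]


def save_block_manifest(blocks: Sequence[SliceBlock], path: Union[str, Path]) -> Path:
    """Serialize block provenance (case_id, start_index, n) as JSON."""
    path = Path(path)
    records = [{"case_id": b.case_id, "start_index": int(b.start_index), "n": int(b.n)}
               for b in blocks]
    path.write_text(json.dumps(records, indent=1))
    return path


def load_block_manifest(path: Union[str, Path]) -> list[dict]:
    return json.loads(Path(path).read_text())
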