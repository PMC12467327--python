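"""Reading, writing and cataloguing CT volumes and aorta masks.

Volumes are kept in a fixed internal layout ``(slice, row, col)``, 0-based,
with slice order equal to acquisition order.  NRRD is the primary on-disk
dialect (the AVT aorta dataset is distributed as ``.nrrd``); NIfTI is
supported for interchange.  Cases are classified into contrast levels from
the mean Hounsfield value over the ground-truth aorta voxels:

* Level 1 — well contrasted, mean aortic HU strictly above 250;
* Level 2 — poorly/non-contrasted, mean aortic HU in the closed
  interval [100, 250];
* ``"excluded"`` — mean aortic HU below 100 (outside both ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "MaskVolume",
    "CaseManifest",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "classify_level",
]

Level = Union[int, str]  # 1, 2 or "excluded"

_NRRD_SUFFIXES = {".nrrd"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}


@dataclass
class CTVolume:
    """An ordered stack of CT slices in Hounsfield units.

    Parameters
    ----------
    slices : ndarray, shape (S, H, W)
        Per-voxel intensities, Hounsfield units, indexed (slice, row, col).
    voxel_depth : float
        Through-plane spacing (slice thickness), mm.  Must be positive.
    in_plane_spacing : (float, float)
        (row, col) pixel spacing, mm.
    case_id : str
        Identifier of the case the volume belongs to.
    """

    slices: np.ndarray
    voxel_depth: float
    in_plane_spacing: tuple[float, float] = (1.0, 1.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError(
                f"non-3D payload: expected (slice, row, col), got shape {self.slices.shape}"
            )
        if not self.voxel_depth > 0:
            raise ValueError(f"voxel_depth must be > 0, got {self.voxel_depth}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape


@dataclass
class MaskVolume:
    """Binary aorta masks aligned slice-for-slice with a :class:`CTVolume`."""

    masks: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(
                f"non-3D payload: expected (slice, row, col), got shape {self.masks.shape}"
            )
        vals = np.unique(self.masks)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be binary {{0,1}}, found {vals[:10]}")
        self.masks = self.masks.astype(np.uint8, copy=False)

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks.shape


def _infer_format(path: Union[str, Path]) -> str:
    name = str(path).lower()
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(path: Union[str, Path], format: str | None = None) -> CTVolume:
    """Read a CT volume from NRRD or NIfTI into the internal layout.

    ``voxel_depth`` is taken from the file header's through-plane spacing.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    payload that is not a 3-D scalar grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"non-3D payload: {path} has dimension {img.GetDimension()}")
        arr = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, col)
        sx, sy, sz = img.GetSpacing()
        return CTVolume(arr, voxel_depth=float(sz), in_plane_spacing=(float(sy), float(sx)),
                        case_id=path.name.split(".")[0])
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"non-3D payload: {path} has shape {data.shape}")
        # NIfTI stores (x, y, z) fastest-first; transpose to (slice, row, col).
        arr = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()
        return CTVolume(arr, voxel_depth=float(zooms[2]),
                        in_plane_spacing=(float(zooms[1]), float(zooms[0])),
                        case_id=path.name.split(".")[0])
    raise ValueError(f"unknown format {fmt!r}; expected 'nrrd' or 'nifti'")


def write_volume(volume: CTVolume, path: Union[str, Path], format: str | None = None) -> Path:
    """Write a volume so that :func:`read_volume` round-trips it bit-exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.slices)
        sr, sc = volume.in_plane_spacing
        img.SetSpacing((float(sc), float(sr), float(volume.voxel_depth)))
        sitk.WriteImage(img, str(path))
        return path
    if fmt == "nifti":
        import nibabel as nib

        sr, sc = volume.in_plane_spacing
        affine = np.diag([sc, sr, volume.voxel_depth, 1.0])
        data = np.transpose(volume.slices, (2, 1, 0))
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((sc, sr, volume.voxel_depth))
        nib.save(img, str(path))
        return path
    raise ValueError(f"unknown format {fmt!r}; expected 'nrrd' or 'nifti'")


def read_mask(path: Union[str, Path], format: str | None = None) -> MaskVolume:
    """Read a binary mask volume (integer-typed NRRD/NIfTI)."""
    vol = read_volume(path, format=format)
    return MaskVolume(np.rint(vol.slices).astype(np.uint8))


def write_mask(mask: MaskVolume, path: Union[str, Path],
               voxel_depth: float = 1.0,
               in_plane_spacing: tuple[float, float] = (1.0, 1.0),
               format: str | None = None) -> Path:
    """Write a mask volume as an integer-typed file; values stay in {0, 1}."""
    carrier = CTVolume(mask.masks.astype(np.uint8), voxel_depth=voxel_depth,
                       in_plane_spacing=in_plane_spacing)
    return write_volume(carrier, path, format=format)


def classify_level(volume: CTVolume, mask: MaskVolume,
                   statistic: str = "mean") -> Level:
    """Classify a case's contrast level from aortic intensity.

    Computes the chosen statistic (default: mean) of the Hounsfield values
    over all ground-truth foreground voxels.  Strictly above 250 HU is
    Level 1; within the closed interval [100, 250] HU is Level 2 (the
    boundary value 250 therefore falls in Level 2); anything below 100 HU
    is ``"excluded"``.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    fg = mask.masks.astype(bool)
    if not fg.any():
        raise ValueError("empty mask: cannot classify a case with no foreground voxels")
    values = volume.slices[fg]
    if statistic == "mean":
        stat = float(np.mean(values))
    elif statistic == "median":
        stat = float(np.median(values))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if stat > 250.0:
        return 1
    if 100.0 <= stat <= 250.0:
        return 2
    return "excluded"


@dataclass
class CaseManifest:
    """A catalogue of cases: id, image path, contrast level, spacing, size."""

    entries: list[dict] = field(default_factory=list)

    COLUMNS = ("case_id", "path", "level", "voxel_depth_mm", "n_slices")

    def add(self, case_id: str, path: Union[str, Path], level: Level,
            voxel_depth: float, n_slices: int, **extra) -> None:
        if any(e["case_id"] == case_id for e in self.entries):
            raise ValueError(f"duplicate case_id {case_id!r} in manifest")
        self.entries.append({
            "case_id": case_id, "path": str(path), "level": level,
            "voxel_depth_mm": float(voxel_depth), "n_slices": int(n_slices),
            **extra,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CaseManifest":
        df = pd.read_csv(path)
        man = cls()
        for rec in df.to_dict("records"):
            lvl = rec["level"]
            rec["level"] = int(lvl) if str(lvl) in ("1", "2") else "excluded"
            man.entries.append(rec)
        return man

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
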