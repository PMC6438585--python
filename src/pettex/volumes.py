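"""PET volume and VOI mask data model, NIfTI I/O and geometry helpers.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` over the ``(x, y, z)`` axes; world
coordinates follow the NIfTI affine.  Intensities are standardized uptake
values (SUV, unitless, >= 0).  Voxel volume in ml is
``dx * dy * dz / 1000`` with spacing in mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Minimum number of voxels for which texture matrices are computed.
#: Smaller VOIs are excluded from the analysis.
MIN_VOXELS = 64


class SegmentationMethod(str, enum.Enum):
    """The three delineation methods compared by the study."""

    FIXED40 = "fixed40"
    ADAPTIVE_SBR = "adaptive"
    GRADIENT_EDGE = "gradient"


@dataclass(frozen=True)
class PETVolume:
    """A 3D PET image in SUV units with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV at each voxel; finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {values.ndim}D")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must be finite")
        if np.any(values < 0):
            raise ValueError("SUV values must be >= 0")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VOIMask:
    """Boolean voxel mask delineating a tumor VOI on a :class:`PETVolume`.

    Carries provenance: which segmentation method produced it and which
    observer initiated the segmentation.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    method: SegmentationMethod | None = None
    observer: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warning: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.mask = mask.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_ml(self) -> float:
        """Metabolic tumor volume (MTV) in ml."""
        return self.n_voxels * self.voxel_volume_ml


@dataclass(frozen=True)
class EligibilityResult:
    """Outcome of the minimum-VOI-size rule for texture analysis."""

    eligible: bool
    n_voxels: int
    min_voxels: int
    min_volume_ml: float


def check_min_volume(mask: VOIMask, min_voxels: int = MIN_VOXELS) -> EligibilityResult:
    """Apply the minimum-size rule: texture matrices need >= 64 voxels.

    The voxel count is the primary rule; the equivalent minimum volume in ml
    (64 voxels at 4.07 x 4.07 x 2 mm is 2.12 ml) is derived from the mask's
    spacing and reported alongside.
    """
    n = mask.n_voxels
    return EligibilityResult(
        eligible=n >= min_voxels,
        n_voxels=n,
        min_voxels=min_voxels,
        min_volume_ml=min_voxels * mask.voxel_volume_ml,
    )


def load_volume(path: str | Path) -> PETVolume:
    """Load a NIfTI-1 PET volume in SUV units.

    Spacing is read from the header zooms; the world offset from the affine
    translation.  Only 3D images are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D from {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return PETVolume(values=data, spacing=zooms, origin=origin)


def save_volume(volume: PETVolume, path: str | Path) -> Path:
    """Write a PETVolume to NIfTI-1 (float64 payload)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine())
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def save_mask(mask: VOIMask, path: str | Path) -> Path:
    """Write a VOI mask to NIfTI-1 as a 0/1 uint8 payload.

    Round-trips losslessly: reloading yields the same boolean array,
    spacing and voxel count.
    """
    path = Path(path)
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path, method: SegmentationMethod | None = None,
              observer: str = "") -> VOIMask:
    """Load a 0/1 NIfTI mask written by :func:`save_mask`."""
    vol = nib.load(str(Path(path)))
    data = np.asarray(vol.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D")
    zooms = tuple(float(z) for z in vol.header.get_zooms()[:3])
    origin = tuple(float(v) for v in vol.affine[:3, 3])
    return VOIMask(mask=data > 0, spacing=zooms, method=method,
                   observer=observer, origin=origin)
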