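"""In-memory containers for PET volumes and tumor masks.

A :class:`PetVolume` is a 3-D scalar field in SUV units together with its
voxel spacing (mm); a :class:`TumorMask` is a binary region on the same
grid.  NIfTI round-tripping goes through nibabel; the affine encodes the
spacing on its diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["PetVolume", "TumorMask"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must have three entries (mm per axis)")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive in every axis, got {spacing}")
    return spacing


@dataclass
class PetVolume:
    """3-D PET image in SUV units on a regular, possibly anisotropic grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("PET volume must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PET volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "PetVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing, np.asarray(img.affine))


@dataclass
class TumorMask:
    """Binary tumor region congruent with its parent :class:`PetVolume`.

    ``provenance`` records whether the mask came from the automatic
    delineation or from an external override; ``meta`` carries algorithm
    diagnostics (final threshold, iterations, oscillation flag ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = "automatic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = _check_spacing(self.spacing)
        if self.provenance not in ("automatic", "override", "ground_truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def check_congruent(self, vol: PetVolume) -> None:
        if self.data.shape != vol.data.shape or not np.allclose(self.spacing, vol.spacing):
            raise ValueError(
                "mask grid does not match volume: "
                f"mask shape {self.data.shape} spacing {self.spacing} vs "
                f"volume shape {vol.data.shape} spacing {vol.spacing}"
            )

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, provenance: str = "override") -> "TumorMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0, spacing, provenance=provenance)
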