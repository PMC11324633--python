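"""Voxel-grid containers for activity and attenuation maps.

Conventions (fixed package-wide): volumes are indexed ``[ix, iy, iz]`` with
``z`` the scanner axis, voxels are isotropic, indices are 0-based, and world
coordinates are taken at voxel centers with the origin at the grid center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ActivityVolume", "AttenuationVolume", "voxel_centers_mm"]


def voxel_centers_mm(grid_shape: tuple[int, int, int], voxel_size_mm: float):
    """World coordinates (mm) of voxel centers along each axis.

    The origin sits at the center of the grid, so a ``(54, 54, 48)`` grid at
    9.6 mm spans roughly ±254 mm in-plane.
    """
    return tuple(
        (np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in grid_shape
    )


@dataclass
class _Volume:
    values: np.ndarray
    voxel_size_mm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def total(self) -> float:
        return float(self.values.sum())

    def same_grid(self, other: "_Volume") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and abs(self.voxel_size_mm - other.voxel_size_mm) < 1e-9
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI with the voxel size in the affine."""
        s = self.voxel_size_mm
        affine = np.diag([s, s, s, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if max(zooms) - min(zooms) > 1e-4:
            raise ValueError("only isotropic voxels are supported")
        return cls(np.asarray(img.dataobj, dtype=np.float64), float(zooms[0]))

    def to_raw(self, path: str | Path) -> None:
        """Write raw float32 with a JSON sidecar describing the grid."""
        path = Path(path)
        self.values.astype(np.float32).tofile(path)
        sidecar = {
            "shape": list(self.grid_shape),
            "dtype": "float32",
            "order": "C",
            "voxel_size_mm": self.voxel_size_mm,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_raw(cls, path: str | Path):
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
        return cls(values.astype(np.float64), float(meta["voxel_size_mm"]))


@dataclass
class ActivityVolume(_Volume):
    """Activity per voxel in MBq.

    ``is_difference`` marks volumes that represent a subtraction result and
    may legitimately contain negative voxels; all other activity volumes are
    validated to be non-negative.
    """

    is_difference: bool = False

    def __post_init__(self):
        super().__post_init__()
        if not self.is_difference and self.values.min() < 0:
            raise ValueError("activity volume has negative voxels")


@dataclass
class AttenuationVolume(_Volume):
    """Linear attenuation coefficients at 140 keV, in mm^-1."""

    def __post_init__(self):
        super().__post_init__()
        if self.values.min() < 0:
            raise ValueError("attenuation coefficients must be non-negative")
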