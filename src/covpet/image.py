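"""Core image containers and NIfTI-1 I/O.

Volumes live on regular 3D grids with per-axis voxel spacing in millimetres.
All scans entering a joint analysis are assumed already co-registered to a
common space: same grid shape, same spacing.  Spatial normalization and
registration are outside the scope of this package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

Triple = tuple[float, float, float]


@dataclass
class Scan:
    """A 3D PET volume.

    Parameters
    ----------
    values
        Non-negative voxel intensities, shape ``(nx, ny, nz)``.
    spacing_mm
        Voxel edge lengths along each axis, in mm.
    id
        Subject/scan identifier used in tabular outputs.
    units
        ``"SUV"`` for calibrated standardized-uptake-value volumes,
        ``"arbitrary"`` otherwise (brain scans are typically relative).
    """

    values: np.ndarray
    spacing_mm: Triple
    id: str = ""
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("scan must be a 3D volume")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"scan {self.id!r}: non-finite voxel values")
        if np.any(self.values < 0):
            raise ValueError(f"scan {self.id!r}: negative voxel values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class Mask:
    """A boolean region-of-interest volume (e.g. the whole-brain mask)."""

    indicator: np.ndarray
    spacing_mm: Triple

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.n_voxels < 1:
            raise ValueError("empty mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml

    def fingerprint(self) -> str:
        """Stable hash of shape, spacing and voxel membership.

        Masked voxel vectors are always linearized in C order; the
        fingerprint ties a stored pattern to the exact grid and ordering
        it was derived on, so prospective scoring can refuse mismatched
        inputs instead of silently resampling.
        """
        h = hashlib.sha1()
        h.update(repr(self.shape).encode())
        h.update(repr(self.spacing_mm).encode())
        h.update(b"C-order")
        h.update(np.packbits(self.indicator.ravel(order="C")).tobytes())
        return h.hexdigest()


def _affine(spacing_mm: Triple) -> np.ndarray:
    return np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])


def save_scan(scan: Scan, path: str | Path) -> Path:
    """Write a scan as NIfTI-1 with spacing carried in the header."""
    path = Path(path)
    img = nib.Nifti1Image(scan.values.astype(np.float64), _affine(scan.spacing_mm))
    img.header.set_zooms(scan.spacing_mm)
    nib.save(img, str(path))
    return path


def load_scan(path: str | Path, id: str | None = None, units: str = "arbitrary") -> Scan:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    scan_id = id if id is not None else path.name.split(".")[0]
    return Scan(values=values, spacing_mm=spacing, id=scan_id, units=units)


def save_mask(mask: Mask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.indicator.astype(np.uint8), _affine(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    indicator = np.asarray(img.get_fdata()) > 0.5
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask(indicator=indicator, spacing_mm=spacing)
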