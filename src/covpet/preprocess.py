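"""Preprocessing of co-registered PET volumes.

The analysis representation of a brain scan is the natural log of its
globally normalized intensities over a common brain mask:

1. isotropic Gaussian smoothing (default FWHM 10 mm),
2. whole-brain mask computed from the data (or supplied by the user),
3. division by the scan's mean over the mask ("whole brain as reference"
   intensity normalization — PET brain scans are relative, not quantitative),
4. natural log at masked voxels, linearized in C order.

Normalization makes every downstream expression score invariant to
multiplying a scan by a positive constant.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .image import Mask, Scan

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: default data-driven mask threshold, as a fraction of each scan's
#: mean over its positive voxels
DEFAULT_MASK_FRACTION = 0.2


def smooth_gaussian(scan: Scan, fwhm_mm: float) -> Scan:
    """Smooth with an isotropic (in mm) Gaussian kernel of the given FWHM.

    Sigma per axis is ``fwhm / (2*sqrt(2 ln 2)) / spacing`` voxels, so
    anisotropic grids get anisotropic voxel sigmas but an isotropic
    physical kernel.  The boundary is handled by renormalization: the
    volume is filtered with zero padding and divided by the identically
    filtered indicator of the grid, so a constant volume is preserved
    exactly and edge voxels are averages of in-grid data only.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in scan.spacing_mm]
    num = ndimage.gaussian_filter(scan.values, sigma=sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(
        np.ones_like(scan.values), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return Scan(
        values=num / den, spacing_mm=scan.spacing_mm, id=scan.id, units=scan.units
    )


def compute_mask(scans: list[Scan], fraction: float = DEFAULT_MASK_FRACTION) -> Mask:
    """Common-support mask: intersection of per-scan threshold masks.

    A voxel is kept iff, in *every* scan, its value exceeds ``fraction``
    times that scan's mean over its positive voxels.  The intersection
    guarantees that masked log intensities are well defined for all
    subjects in the cohort.
    """
    if not scans:
        raise ValueError("need at least one scan")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    shape = scans[0].shape
    spacing = scans[0].spacing_mm
    keep = np.ones(shape, dtype=bool)
    for scan in scans:
        if scan.shape != shape or scan.spacing_mm != spacing:
            raise ValueError("scans must share shape and spacing")
        positive = scan.values > 0
        if not positive.any():
            raise ValueError("empty mask: scan has no positive voxels")
        threshold = fraction * scan.values[positive].mean()
        keep &= scan.values > threshold
    if not keep.any():
        raise ValueError("empty mask")
    return Mask(indicator=keep, spacing_mm=spacing)


def normalize_global(scan: Scan, mask: Mask) -> Scan:
    """Divide by the scan's mean over the mask (whole-brain reference).

    The masked mean of the output is exactly 1, and the operation is
    scale invariant: ``c * scan`` maps to the same output for any c > 0.
    """
    if scan.shape != mask.shape:
        raise ValueError("scan and mask shapes differ")
    masked_mean = scan.values[mask.indicator].mean()
    if not masked_mean > 0:
        raise ValueError("nonpositive masked mean; cannot normalize")
    return Scan(
        values=scan.values / masked_mean,
        spacing_mm=scan.spacing_mm,
        id=scan.id,
        units=scan.units,
    )


def log_transform(scan: Scan, mask: Mask, floor: float | None = None) -> np.ndarray:
    """Natural log of masked voxels, as a 1D vector in C order.

    Values below ``floor`` are clipped to it before the log; smoothed
    volumes can underflow to ~0 at the mask edge and a hard error there
    would be brittle.  The default floor is 1e-6 of the masked mean.  A
    warning reports how many voxels were floored.
    """
    if scan.shape != mask.shape:
        raise ValueError("scan and mask shapes differ")
    masked = scan.values.ravel(order="C")[mask.indicator.ravel(order="C")]
    if floor is None:
        floor = 1e-6 * masked.mean()
    if not floor > 0:
        raise ValueError("floor must be positive")
    n_floored = int((masked < floor).sum())
    if n_floored:
        warnings.warn(
            f"scan {scan.id!r}: {n_floored} masked voxel(s) below floor "
            f"{floor:g}; clipped before log",
            stacklevel=2,
        )
    return np.log(np.maximum(masked, floor))
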