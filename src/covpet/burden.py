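"""Lesion segmentation and metabolic burden metrics on whole-body SUV volumes.

FDG-avid lesions are delineated with a percentage-of-SUVmax isocontour:
each lesion is the 26-connected component, around a detected uptake peak,
of voxels at or above ``fraction`` (default 0.41) of that peak's SUV.
Tissues with high physiological uptake (brain, myocardium, bladder,
kidney) are handled through a user-supplied exclusion mask, applied as
given — focal uptake the user wants kept simply stays outside the mask.

Burden metrics follow the standard definitions:

* TMTV (mL): summed volume of all lesion voxels,
* SUVmean / SUVmax over lesion voxels,
* TLG = TMTV x SUVmean,
* lg(TMTV), lg(TLG): base-10 logs, reported as missing when TMTV = 0.

Whole-brain glycolysis (TBG) is the analogous product for the brain:
brain metabolic volume (mL) x brain SUVmean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Mask, Scan

DEFAULT_FRACTION = 0.41
DEFAULT_MIN_SUV = 2.5

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionRecord:
    label: int
    peak_index: tuple[int, int, int]
    peak_suv: float
    n_voxels: int
    volume_ml: float
    suv_mean: float
    suv_max: float


@dataclass
class LesionSegmentation:
    """Integer label volume (0 background, 1..K lesions) plus per-lesion records."""

    labels: np.ndarray
    lesions: list[LesionRecord]
    spacing_mm: tuple[float, float, float]

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class BurdenMetrics:
    """Tumor burden summary; log fields are None when no lesion was found."""

    tmtv_ml: float
    suv_max: float
    suv_mean: float
    tlg: float
    lg_tmtv: float | None
    lg_tlg: float | None
    n_lesions: int


@dataclass
class BrainGlycolysis:
    suv_max: float
    suv_mean: float
    volume_ml: float
    tbg: float


def detect_peaks(
    scan: Scan,
    exclusion_mask: np.ndarray | None = None,
    min_suv: float = DEFAULT_MIN_SUV,
) -> list[tuple[int, int, int]]:
    """Automatic uptake peaks: 26-neighborhood local maxima with SUV >= min_suv.

    This is a reproducible stand-in for manual seed placement.  Flat
    plateaus (phantom lesions painted at constant SUV) yield one peak per
    connected plateau: the voxel nearest the plateau centroid, ties broken
    by lexicographic coordinate.  Peaks inside the exclusion mask are not
    reported.
    """
    v = scan.values
    local_max = v == ndimage.maximum_filter(v, footprint=_CONN26, mode="constant", cval=-np.inf)
    candidate = local_max & (v >= min_suv)
    if exclusion_mask is not None:
        candidate &= ~np.asarray(exclusion_mask, dtype=bool)
    if not candidate.any():
        return []
    # group contiguous equal-valued candidates into single plateau peaks
    plateau_labels, n = ndimage.label(candidate, structure=_CONN26)
    peaks: list[tuple[int, int, int]] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(plateau_labels == lab)
        coords = coords[np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))]
        d2 = ((coords - coords.mean(axis=0)) ** 2).sum(axis=1)
        best = coords[int(np.argmin(d2))]  # first minimum = lexicographic tie-break
        peaks.append(tuple(int(c) for c in best))
    peaks.sort(key=lambda p: (-v[p], p))
    return peaks


def segment_lesion(
    scan: Scan, peak: tuple[int, int, int], fraction: float = DEFAULT_FRACTION
) -> np.ndarray:
    """Isocontour segment: the 26-connected region containing ``peak`` among
    voxels with SUV >= fraction x SUV(peak)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    peak = tuple(int(c) for c in peak)
    threshold = fraction * scan.values[peak]
    above = scan.values >= threshold
    labels, _ = ndimage.label(above, structure=_CONN26)
    return labels == labels[peak]


def segment_all(
    scan: Scan,
    exclusion_mask: np.ndarray | None = None,
    fraction: float = DEFAULT_FRACTION,
    min_suv: float = DEFAULT_MIN_SUV,
    seeds: list[tuple[int, int, int]] | None = None,
) -> LesionSegmentation:
    """Detect peaks (or take user ``seeds``), segment each, merge overlaps.

    Peaks whose isocontour regions overlap are merged into one lesion;
    the merged lesion's recorded peak is its highest-SUV voxel.  Final
    labels are deterministic: 1..K sorted by peak SUV descending, then by
    peak coordinate.
    """
    peaks = (
        [tuple(int(c) for c in p) for p in seeds]
        if seeds is not None
        else detect_peaks(scan, exclusion_mask, min_suv)
    )
    labels = np.zeros(scan.shape, dtype=np.int32)
    next_label = 1
    for peak in peaks:  # peaks ordered by SUV desc, coordinate
        region = segment_lesion(scan, peak, fraction)
        overlapping = np.unique(labels[region])
        overlapping = overlapping[overlapping > 0]
        if overlapping.size:
            target = int(overlapping.min())  # earliest label = highest peak
            for other in overlapping:
                if other != target:
                    labels[labels == other] = target
            labels[region & (labels == 0)] = target
        else:
            labels[region] = next_label
            next_label += 1

    records: list[LesionRecord] = []
    voxel_ml = float(np.prod(scan.spacing_mm)) / 1000.0
    for lab in np.unique(labels):
        if lab == 0:
            continue
        member = labels == lab
        suvs = scan.values[member]
        peak_flat = np.argwhere(member & (scan.values == suvs.max()))
        peak_idx = tuple(int(c) for c in peak_flat[np.lexsort(peak_flat.T[::-1])][0])
        records.append(
            LesionRecord(
                label=int(lab),
                peak_index=peak_idx,
                peak_suv=float(suvs.max()),
                n_voxels=int(member.sum()),
                volume_ml=float(member.sum()) * voxel_ml,
                suv_mean=float(suvs.mean()),
                suv_max=float(suvs.max()),
            )
        )
    # relabel 1..K by peak SUV desc then coordinate
    records.sort(key=lambda r: (-r.peak_suv, r.peak_index))
    relabelled = np.zeros_like(labels)
    for new_lab, rec in enumerate(records, start=1):
        relabelled[labels == rec.label] = new_lab
        rec.label = new_lab
    return LesionSegmentation(labels=relabelled, lesions=records, spacing_mm=scan.spacing_mm)


def burden_metrics(segmentation: LesionSegmentation, scan: Scan) -> BurdenMetrics:
    """TMTV / SUV statistics / TLG over all segmented lesion voxels."""
    member = segmentation.labels > 0
    n_vox = int(member.sum())
    if n_vox == 0:
        return BurdenMetrics(
            tmtv_ml=0.0, suv_max=0.0, suv_mean=0.0, tlg=0.0,
            lg_tmtv=None, lg_tlg=None, n_lesions=0,
        )
    tmtv = n_vox * segmentation.voxel_volume_ml
    suvs = scan.values[member]
    suv_mean = float(suvs.mean())
    tlg = tmtv * suv_mean
    return BurdenMetrics(
        tmtv_ml=tmtv,
        suv_max=float(suvs.max()),
        suv_mean=suv_mean,
        tlg=tlg,
        lg_tmtv=float(np.log10(tmtv)),
        lg_tlg=float(np.log10(tlg)),
        n_lesions=segmentation.n_lesions,
    )


def brain_glycolysis(
    scan: Scan, brain_mask: Mask, suv_threshold: float | None = None
) -> BrainGlycolysis:
    """Whole-brain glycolysis: brain metabolic volume x brain SUVmean.

    The brain metabolic volume is taken as the full brain-mask volume by
    default; ``suv_threshold`` optionally restricts it to voxels at or
    above a SUV cutoff.
    """
    if scan.shape != brain_mask.shape:
        raise ValueError("scan and brain mask shapes differ")
    member = brain_mask.indicator.copy()
    if suv_threshold is not None:
        member &= scan.values >= suv_threshold
    if not member.any():
        raise ValueError("empty brain region after thresholding")
    suvs = scan.values[member]
    volume_ml = float(member.sum()) * brain_mask.voxel_volume_ml
    suv_mean = float(suvs.mean())
    return BrainGlycolysis(
        suv_max=float(suvs.max()),
        suv_mean=suv_mean,
        volume_ml=volume_ml,
        tbg=volume_ml * suv_mean,
    )
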