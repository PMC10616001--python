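"""Prospective single-scan pattern expression (topographic profile rating).

A stored covariance pattern can be applied to any new scan on the same
grid: the scan is globally normalized, log-transformed over the pattern's
mask, centered by its own masked mean, the derivation group-mean profile is
subtracted, and the raw expression score is the inner product with the
pattern weights.  Because this repeats the derivation bookkeeping exactly,
forward-scoring a derivation subject reproduces its derivation score to
floating-point round-off.

Raw scores are Z-transformed against the pattern's stored reference
(control mean/SD by default), so a Z of 0 means "expresses the pattern like
an average reference subject" and each unit is one reference SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .image import Scan
from .ssm import CovariancePattern


@dataclass
class ExpressionScore:
    """One subject's pattern expression at one timepoint."""

    id: str
    raw: float
    z: float
    timepoint: str = "baseline"


def tpr_score(pattern: CovariancePattern, scan: Scan, floor: float | None = None) -> float:
    """Raw expression score of a single (already smoothed) scan.

    The scan must live on the pattern's exact grid: shape, spacing and
    voxel ordering are checked through the mask fingerprint and a mismatch
    is an error — scans are never silently resampled.
    """
    if scan.shape != pattern.mask.shape or scan.spacing_mm != pattern.mask.spacing_mm:
        raise ValueError(
            f"scan {scan.id!r} does not match the pattern grid "
            f"(fingerprint {pattern.mask_fingerprint[:12]})"
        )
    log_vec = preprocess.log_transform(
        preprocess.normalize_global(scan, pattern.mask), pattern.mask, floor
    )
    residual = (log_vec - log_vec.mean()) - pattern.gmp
    return float(pattern.weights @ residual)


def zscore(raw_scores: np.ndarray, z_ref: tuple[float, float]) -> np.ndarray:
    """Affine Z transform against a stored (mean, SD) reference."""
    mean, sd = z_ref
    if not sd > 0:
        raise ValueError("z_ref SD must be positive")
    return (np.asarray(raw_scores, dtype=np.float64) - mean) / sd


def score_scans(
    pattern: CovariancePattern,
    scans: list[Scan],
    timepoint: str = "baseline",
    smoothed: bool = False,
) -> pd.DataFrame:
    """Score a batch of scans; returns columns ``id, timepoint, raw, z``.

    Unless ``smoothed=True``, each scan is first smoothed with the FWHM
    recorded in the pattern's provenance so prospective preprocessing
    matches derivation preprocessing.
    """
    fwhm = pattern.provenance.get("fwhm_mm")
    rows = []
    for scan in scans:
        if not smoothed and fwhm is not None:
            scan = preprocess.smooth_gaussian(scan, float(fwhm))
        raw = tpr_score(pattern, scan)
        rows.append(
            {
                "id": scan.id,
                "timepoint": timepoint,
                "raw": raw,
                "z": float(zscore(np.array([raw]), pattern.z_ref)[0]),
            }
        )
    return pd.DataFrame(rows, columns=["id", "timepoint", "raw", "z"])


def score_change(baseline: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-subject post-treatment decline in pattern expression.

    Pairs rows by subject ``id`` and returns ``decline = baseline z - post z``
    (positive = expression decreased after treatment).  Any unpaired id on
    either side is an error.
    """
    b = baseline.set_index("id")
    p = post.set_index("id")
    unpaired = set(b.index).symmetric_difference(p.index)
    if unpaired:
        raise ValueError(f"unpaired subject ids: {sorted(unpaired)}")
    ids = list(b.index)
    return pd.DataFrame(
        {
            "id": ids,
            "baseline_z": b.loc[ids, "z"].to_numpy(),
            "post_z": p.loc[ids, "z"].to_numpy(),
            "decline": b.loc[ids, "z"].to_numpy() - p.loc[ids, "z"].to_numpy(),
        }
    )
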