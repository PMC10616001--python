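"""Scaled-subprofile-model PCA: derive a disease-related covariance pattern.

The derivation pipeline for a labeled cohort of preprocessed brain scans:

1. stack masked log intensities into a subject-by-voxel matrix,
2. double-center it: remove each row's mean (the subject global offset)
   then each column's mean across subjects (the stored *group mean
   profile*, GMP) — the doubly centered rows are the *subject residual
   profiles* (SRP),
3. PCA of the SRP matrix (computed via SVD, which is the subject-space
   route; contractually equal to the voxel-space eigendecomposition up to
   sign),
4. combine the leading components — the smallest prefix reaching a
   cumulative variance-accounted-for cutoff (default 50%) — with Fisher
   linear discriminant coefficients that maximally separate patients from
   controls in component-score space,
5. normalize to a unit-norm voxel weight map, orient it so patients score
   higher than controls, and store the control score mean/SD as the
   Z-reference.

The resulting :class:`CovariancePattern` carries everything needed to score
a new scan prospectively (see :mod:`covpet.scoring`) with bit-identical
bookkeeping: GMP, mask fingerprint, voxel ordering and Z-reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import Mask, Scan, save_mask, load_mask
from . import preprocess

DEFAULT_VAF_CUTOFF = 0.5
_RIDGE = 1e-8


@dataclass
class SubjectMatrix:
    """Masked log intensities, one row per subject."""

    data: np.ndarray  # (subjects, masked voxels)
    labels: list[str]  # "control" / "patient" per row
    ids: list[str]
    mask: Mask

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("subject matrix must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("subject matrix contains non-finite entries")
        if len(self.labels) != self.data.shape[0] or len(self.ids) != self.data.shape[0]:
            raise ValueError("labels/ids must match the number of rows")
        for group in ("control", "patient"):
            if self.labels.count(group) < 3:
                raise ValueError(f"need at least 3 subjects in group {group!r}")


@dataclass
class ResidualProfiles:
    """Doubly centered data (SRP) and the column-mean reference (GMP)."""

    srp: np.ndarray
    gmp: np.ndarray
    row_means: np.ndarray

    def __post_init__(self) -> None:
        for axis, name in ((1, "row"), (0, "column")):
            worst = np.abs(self.srp.mean(axis=axis)).max()
            if worst > 1e-8:
                raise ValueError(f"SRP {name} means not zero (max |mean| = {worst:g})")


@dataclass
class ComponentSet:
    """Principal components of the SRP matrix."""

    loadings: np.ndarray  # (components, voxels), orthonormal rows
    subject_scores: np.ndarray  # (subjects, components) == srp @ loadings.T
    vaf: np.ndarray  # variance fraction per component, sums to 1

    def __post_init__(self) -> None:
        k = self.loadings.shape[0]
        gram = self.loadings @ self.loadings.T
        if np.abs(gram - np.eye(k)).max() > 1e-8:
            raise ValueError("loadings are not orthonormal")
        if abs(self.vaf.sum() - 1.0) > 1e-8:
            raise ValueError("VAF must sum to 1 over retained components")


@dataclass
class CovariancePattern:
    """A derived metabolic covariance pattern plus scoring bookkeeping.

    ``weights`` is the unit-norm voxel weight map (the pattern topography),
    oriented so patients express it more than controls.  ``z_ref`` holds the
    reference (mean, SD) used to Z-transform raw expression scores; under
    the default control-referenced convention these are the control raw
    score mean and SD.
    """

    weights: np.ndarray  # (masked voxels,), unit norm
    gmp: np.ndarray
    mask: Mask
    z_ref: tuple[float, float]
    component_indices: list[int]
    coefficients: np.ndarray
    z_convention: str = "control"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.weights) - 1.0) > 1e-8:
            raise ValueError("pattern weights must have unit norm")
        if not self.z_ref[1] > 0:
            raise ValueError("z_ref SD must be positive")

    @property
    def mask_fingerprint(self) -> str:
        return self.mask.fingerprint()

    def weight_volume(self) -> np.ndarray:
        """Full-grid weight map, zero at unmasked voxels."""
        vol = np.zeros(self.mask.shape, dtype=np.float64)
        vol[self.mask.indicator] = self.weights
        return vol

    def save(self, out_dir: str | Path) -> Path:
        """Write the sidecar pair: NIfTI maps + JSON metadata."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wvol = self.weight_volume()
        # weight/GMP maps may be negative; bypass the Scan non-negativity
        # contract by writing NIfTI directly
        import nibabel as nib

        affine = np.diag([*self.mask.spacing_mm, 1.0])
        nib.save(nib.Nifti1Image(wvol, affine), str(out_dir / "weights.nii.gz"))
        gvol = np.zeros(self.mask.shape, dtype=np.float64)
        gvol[self.mask.indicator] = self.gmp
        nib.save(nib.Nifti1Image(gvol, affine), str(out_dir / "gmp.nii.gz"))
        save_mask(self.mask, out_dir / "mask.nii.gz")
        meta = {
            "z_ref": {"mean": self.z_ref[0], "sd": self.z_ref[1]},
            "z_convention": self.z_convention,
            "component_indices": self.component_indices,
            "coefficients": list(map(float, self.coefficients)),
            "mask_fingerprint": self.mask_fingerprint,
            "voxel_order": "C",
            "provenance": self.provenance,
        }
        (out_dir / "pattern.json").write_text(json.dumps(meta, indent=2))
        return out_dir

    @classmethod
    def load(cls, in_dir: str | Path) -> "CovariancePattern":
        import nibabel as nib

        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "pattern.json").read_text())
        mask = load_mask(in_dir / "mask.nii.gz")
        wvol = np.asarray(nib.load(str(in_dir / "weights.nii.gz")).get_fdata())
        gvol = np.asarray(nib.load(str(in_dir / "gmp.nii.gz")).get_fdata())
        pattern = cls(
            weights=wvol[mask.indicator],
            gmp=gvol[mask.indicator],
            mask=mask,
            z_ref=(meta["z_ref"]["mean"], meta["z_ref"]["sd"]),
            component_indices=list(meta["component_indices"]),
            coefficients=np.asarray(meta["coefficients"], dtype=np.float64),
            z_convention=meta["z_convention"],
            provenance=meta.get("provenance", {}),
        )
        if pattern.mask_fingerprint != meta["mask_fingerprint"]:
            raise ValueError("pattern sidecar corrupt: mask fingerprint mismatch")
        return pattern


def build_matrix(
    scans: list[Scan],
    mask: Mask,
    labels: list[str],
    floor: float | None = None,
) -> SubjectMatrix:
    """Stack preprocessed scans into a subject-by-voxel log matrix.

    Each row is ``log_transform(normalize_global(scan))`` over the common
    mask, in C voxel order — exactly the representation prospective
    scoring recomputes for a new scan.
    """
    if len(scans) != len(labels):
        raise ValueError("scans and labels must align")
    rows = [
        preprocess.log_transform(preprocess.normalize_global(scan, mask), mask, floor)
        for scan in scans
    ]
    return SubjectMatrix(
        data=np.vstack(rows),
        labels=list(labels),
        ids=[scan.id for scan in scans],
        mask=mask,
    )


def double_center(matrix: SubjectMatrix) -> ResidualProfiles:
    """Remove row means (subject offsets) then column means (the GMP)."""
    row_means = matrix.data.mean(axis=1, keepdims=True)
    centered = matrix.data - row_means
    gmp = centered.mean(axis=0)
    srp = centered - gmp
    return ResidualProfiles(srp=srp, gmp=gmp, row_means=row_means.ravel())


def principal_components(residuals: ResidualProfiles) -> ComponentSet:
    """PCA of the SRP matrix via thin SVD.

    The SVD route works in subject space (cost grows with subjects, not
    voxels) yet yields exactly the voxel-space covariance eigenvectors:
    for ``srp = U S V^T`` the voxel-space covariance ``srp^T srp`` has
    eigenvectors V with eigenvalues S^2.  Components are ordered by
    decreasing variance; numerically null directions are dropped.  Each
    loading's sign is fixed deterministically: the largest-magnitude
    coefficient is made positive.
    """
    srp = residuals.srp
    if not np.any(srp):
        raise ValueError("no variance: SRP matrix is identically zero")
    u, s, vt = np.linalg.svd(srp, full_matrices=False)
    # drop null-space directions (double-centering kills >= 1 dimension)
    keep = s > s[0] * 1e-10
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s  # == srp @ vt.T
    vaf = s**2 / np.sum(s**2)
    return ComponentSet(loadings=vt, subject_scores=scores, vaf=vaf)


def derive_pattern(
    components: ComponentSet,
    residuals: ResidualProfiles,
    matrix: SubjectMatrix,
    vaf_cutoff: float = DEFAULT_VAF_CUTOFF,
    z_convention: str = "control",
    provenance: dict | None = None,
) -> tuple[CovariancePattern, np.ndarray, np.ndarray]:
    """Combine leading components into the discriminating pattern.

    Candidate components are the smallest prefix whose cumulative VAF
    reaches ``vaf_cutoff``; their combination coefficients are the Fisher
    linear discriminant of the group labels in candidate score space
    (pooled within-group covariance, small ridge for numerical safety).
    Returns ``(pattern, raw_scores, z_scores)`` for the derivation cohort.

    ``z_convention``: ``"control"`` references Z scores to the control raw
    score mean/SD (controls then have Z mean 0, SD 1 by construction);
    ``"pooled"`` references to the whole derivation sample instead.
    """
    if z_convention not in ("control", "pooled"):
        raise ValueError("z_convention must be 'control' or 'pooled'")
    if not 0 < vaf_cutoff <= 1:
        raise ValueError("vaf_cutoff must be in (0, 1]")
    labels = np.asarray(matrix.labels)
    is_patient = labels == "patient"
    is_control = labels == "control"

    cum = np.cumsum(components.vaf)
    n_cand = int(np.searchsorted(cum, vaf_cutoff) + 1)
    n_cand = min(n_cand, len(components.vaf))
    cand = list(range(n_cand))
    scores_cand = components.subject_scores[:, cand]

    mean_p = scores_cand[is_patient].mean(axis=0)
    mean_c = scores_cand[is_control].mean(axis=0)
    scat_p = np.atleast_2d(np.cov(scores_cand[is_patient], rowvar=False)) * (
        is_patient.sum() - 1
    )
    scat_c = np.atleast_2d(np.cov(scores_cand[is_control], rowvar=False)) * (
        is_control.sum() - 1
    )
    pooled = (scat_p + scat_c) / (len(labels) - 2)
    pooled = pooled + _RIDGE * np.eye(n_cand)
    try:
        coeff = np.linalg.solve(pooled, mean_p - mean_c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise ValueError("singular within-group covariance") from exc
    if not np.all(np.isfinite(coeff)) or np.linalg.norm(coeff) == 0:
        raise ValueError("degenerate discriminant: groups are indistinguishable")

    weights = components.loadings[cand].T @ coeff
    weights = weights / np.linalg.norm(weights)
    raw = residuals.srp @ weights
    if raw[is_patient].mean() < raw[is_control].mean():
        weights = -weights
        coeff = -coeff
        raw = -raw

    if z_convention == "control":
        ref_mean = float(raw[is_control].mean())
        ref_sd = float(raw[is_control].std(ddof=1))
    else:
        ref_mean = float(raw.mean())
        ref_sd = float(raw.std(ddof=1))
    if not ref_sd > 0:
        raise ValueError("zero-variance reference scores; cannot define Z")
    z = (raw - ref_mean) / ref_sd

    pattern = CovariancePattern(
        weights=weights,
        gmp=residuals.gmp,
        mask=matrix.mask,
        z_ref=(ref_mean, ref_sd),
        component_indices=cand,
        coefficients=coeff,
        z_convention=z_convention,
        provenance={
            "n_control": int(is_control.sum()),
            "n_patient": int(is_patient.sum()),
            "vaf_cutoff": vaf_cutoff,
            "candidate_vaf": [float(v) for v in components.vaf[cand]],
            **(provenance or {}),
        },
    )
    return pattern, raw, z


def derive(
    scans: list[Scan],
    labels: list[str],
    fwhm_mm: float = 10.0,
    mask_fraction: float = preprocess.DEFAULT_MASK_FRACTION,
    mask: Mask | None = None,
    vaf_cutoff: float = DEFAULT_VAF_CUTOFF,
    z_convention: str = "control",
) -> tuple[CovariancePattern, np.ndarray, np.ndarray]:
    """End-to-end derivation from raw co-registered scans.

    Smooths every scan, computes (or accepts) the common brain mask, builds
    the log matrix, and runs the SSM-PCA chain.  Returns
    ``(pattern, raw_scores, z_scores)``; the pattern records the smoothing
    FWHM so prospective scoring can apply identical preprocessing.
    """
    smoothed = [preprocess.smooth_gaussian(s, fwhm_mm) for s in scans]
    if mask is None:
        mask = preprocess.compute_mask(smoothed, mask_fraction)
    matrix = build_matrix(smoothed, mask, labels)
    residuals = double_center(matrix)
    components = principal_components(residuals)
    return derive_pattern(
        components,
        residuals,
        matrix,
        vaf_cutoff=vaf_cutoff,
        z_convention=z_convention,
        provenance={"fwhm_mm": fwhm_mm, "mask_fraction": mask_fraction},
    )
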