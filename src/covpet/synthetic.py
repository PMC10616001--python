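"""Synthetic PET cohorts and phantoms with known ground truth.

Two generators make every downstream stage testable without clinical data:

* **Brain cohorts** follow the log-linear subject-by-voxel model that
  underlies scaled-subprofile analysis.  For subject ``s`` and masked
  voxel ``v``::

      scan[s, v] = exp(mu[v] + alpha_s + z_s * p[v] + eps[s, v])

  where ``mu`` is the template log profile, ``alpha_s ~ N(0, sigma_global^2)``
  a subject-specific global scaling offset, ``p`` a planted zero-mean
  unit-norm spatial pattern, ``z_s`` the subject's pattern expression
  (standard normal in controls, ``N(delta, tau^2)`` in patients), and
  ``eps`` i.i.d. voxel log-noise.  Because the model is multiplicative with
  a subject global factor, double-centering of the log data provably
  removes ``alpha_s``, and pattern derivation can be validated against the
  planted ``p`` and ``z``.

* **Whole-body SUV phantoms** paint ellipsoidal (or box) hypermetabolic
  lesions — and optional physiological-uptake "organs" to be excluded
  downstream — onto a uniform background.  Voxel membership is decided by
  voxel-center inclusion, so metabolic tumor volume ground truth is an
  exact voxel count.

Neither generator attempts anatomical realism, partial-volume effects or
scanner noise; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Mask, Scan, Triple

# Default cohort sizes: one derivation cohort of 49 controls and 64 patients.
DEFAULT_N_CONTROL = 49
DEFAULT_N_PATIENT = 64

# Default patient expression distribution, N(delta, tau^2).  Chosen to echo
# an observed patient Z-score distribution of roughly 1.3 +/- 0.9 relative
# to controls at N(0, 1); fixture choices, not claims about any population.
DEFAULT_DELTA = 1.3
DEFAULT_TAU = 0.9


@dataclass
class PhantomTemplate:
    """Deterministic brain-like template: ellipsoidal mask + mean log profile.

    ``mu`` is higher in an interior "gray matter" shell than in the
    "white matter" core, giving the mask a non-trivial but smooth mean
    profile.
    """

    grid_shape: tuple[int, int, int]
    spacing_mm: Triple
    mu: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.brain_mask.any():
            raise ValueError("empty brain mask")
        if not np.all(np.isfinite(self.mu[self.brain_mask])):
            raise ValueError("mu must be finite inside the brain mask")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def mask(self) -> Mask:
        return Mask(indicator=self.brain_mask, spacing_mm=self.spacing_mm)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centered physical coordinates of every voxel, per axis."""
        axes = [
            (np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.spacing_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


@dataclass
class Blob:
    """One Gaussian focus of the planted pattern.

    ``radius_mm`` is the Gaussian sigma; the blob is truncated at 3 sigma.
    ``polarity`` +1 plants relatively increased metabolic activity, -1
    decreased.
    """

    center_mm: Triple
    radius_mm: float
    polarity: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class PatternSpec:
    """Planted-pattern layout: a list of signed Gaussian blobs."""

    blobs: list[Blob]

    def __post_init__(self) -> None:
        if not self.blobs:
            raise ValueError("pattern spec needs at least one blob")


@dataclass
class CohortConfig:
    """Generative parameters for a two-group brain cohort."""

    n_control: int = DEFAULT_N_CONTROL
    n_patient: int = DEFAULT_N_PATIENT
    delta: float = DEFAULT_DELTA
    tau: float = DEFAULT_TAU
    sigma_noise: float = 0.02
    sigma_global: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_patient < 3:
            raise ValueError("need at least 3 subjects per group for derivation")
        if min(self.tau, self.sigma_noise, self.sigma_global) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SyntheticCohort:
    """Generated scans plus the ground truth used to make them."""

    scans: list[Scan]
    labels: list[str]
    true_scores: np.ndarray
    pattern_truth: np.ndarray  # full-grid volume, zero outside the mask
    template: PhantomTemplate

    def __post_init__(self) -> None:
        if not (len(self.scans) == len(self.labels) == len(self.true_scores)):
            raise ValueError("scans, labels and true_scores must align")


@dataclass
class Solid:
    """An ellipsoid or axis-aligned box painted into a body phantom.

    ``size_mm`` holds the semi-axes (ellipsoid) or half-extents (box).
    A voxel belongs to the solid iff its center lies inside it.
    """

    center_mm: Triple
    size_mm: Triple
    suv: float
    shape: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "box"):
            raise ValueError("shape must be 'ellipsoid' or 'box'")
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("size must be positive")


@dataclass
class LesionPhantomSpec:
    """Whole-body SUV phantom layout."""

    grid_shape: tuple[int, int, int]
    spacing_mm: Triple
    background_suv: float = 0.5
    lesions: list[Solid] = field(default_factory=list)
    organs: list[Solid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background_suv < 0:
            raise ValueError("background SUV must be non-negative")
        for lesion in self.lesions:
            if lesion.suv <= self.background_suv:
                raise ValueError("lesion SUV must exceed background SUV")


def make_template(
    grid_shape: tuple[int, int, int], spacing_mm: Triple = (2.0, 2.0, 2.0)
) -> PhantomTemplate:
    """Build the deterministic ellipsoidal brain template.

    The mask is an ellipsoid with semi-axes 44% of the grid extent; mu is
    log(4) in the core rising to about log(8) in a shell at 80% relative
    radius, a crude gray/white contrast.
    """
    if len(grid_shape) != 3 or any(n < 16 for n in grid_shape):
        raise ValueError("grid too small: need at least 16 voxels per axis")
    grid_shape = tuple(int(n) for n in grid_shape)
    xs, ys, zs = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing_mm)],
        indexing="ij",
    )
    extent = [n * s for n, s in zip(grid_shape, spacing_mm)]
    center = [e / 2.0 for e in extent]
    semi = [0.44 * e for e in extent]
    r2 = (
        ((xs - center[0]) / semi[0]) ** 2
        + ((ys - center[1]) / semi[1]) ** 2
        + ((zs - center[2]) / semi[2]) ** 2
    )
    brain_mask = r2 <= 1.0
    r = np.sqrt(r2)
    # gray shell peaked at 80% relative radius, sigma 0.18
    shell = np.exp(-0.5 * ((r - 0.8) / 0.18) ** 2)
    mu = np.log(4.0) + (np.log(8.0) - np.log(4.0)) * shell
    mu[~brain_mask] = 0.0
    return PhantomTemplate(
        grid_shape=grid_shape,
        spacing_mm=tuple(float(s) for s in spacing_mm),
        mu=mu,
        brain_mask=brain_mask,
    )


def default_pattern_spec(template: PhantomTemplate) -> PatternSpec:
    """Bilateral plus/minus blob layout loosely emulating a lymphoma-related
    topography: relative hypermetabolism in inferior/central structures
    (cerebellum, brainstem, thalamus) and hypometabolism in posterior and
    superior cortex (occipital, parietal, medial frontal/cingulate).

    Coordinates are placed in normalized ellipsoid units so the layout
    scales with any template geometry.
    """
    extent = [n * s for n, s in zip(template.grid_shape, template.spacing_mm)]
    center = [e / 2.0 for e in extent]
    semi = [0.44 * e for e in extent]
    mean_semi = float(np.mean(semi))

    def at(nx: float, ny: float, nz: float) -> Triple:
        return (
            center[0] + nx * semi[0],
            center[1] + ny * semi[1],
            center[2] + nz * semi[2],
        )

    r_big = 0.22 * mean_semi
    r_mid = 0.16 * mean_semi
    blobs = [
        # positive: bilateral cerebellum-like, brainstem-like, thalamus-like
        Blob(at(+0.32, -0.22, -0.52), r_big, +1, 1.0),
        Blob(at(-0.32, -0.22, -0.52), r_big, +1, 1.0),
        Blob(at(0.0, +0.05, -0.58), r_mid, +1, 0.8),
        Blob(at(+0.13, +0.02, -0.05), r_mid, +1, 0.7),
        Blob(at(-0.13, +0.02, -0.05), r_mid, +1, 0.7),
        # negative: bilateral occipital-, parietal-, medial-frontal-like
        Blob(at(+0.30, -0.52, +0.12), r_big, -1, 1.0),
        Blob(at(-0.30, -0.52, +0.12), r_big, -1, 1.0),
        Blob(at(+0.26, -0.12, +0.55), r_big, -1, 0.9),
        Blob(at(-0.26, -0.12, +0.55), r_big, -1, 0.9),
        Blob(at(0.0, +0.38, +0.30), r_mid, -1, 0.8),
    ]
    return PatternSpec(blobs=blobs)


def make_planted_pattern(template: PhantomTemplate, spec: PatternSpec) -> np.ndarray:
    """Render the blob field and standardize it over the brain mask.

    Returns a full-grid volume that is exactly zero-mean and unit
    Euclidean norm over the mask and zero outside it.
    """
    xs, ys, zs = template.voxel_centers_mm()
    mask = template.brain_mask
    field = np.zeros(template.grid_shape, dtype=np.float64)
    for blob in spec.blobs:
        cx, cy, cz = blob.center_mm
        if not _inside_mask(template, blob.center_mm):
            raise ValueError(f"blob center {blob.center_mm} outside the brain mask")
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
        g = np.exp(-0.5 * d2 / blob.radius_mm**2)
        g[d2 > (3.0 * blob.radius_mm) ** 2] = 0.0  # truncate at 3 sigma
        field += blob.polarity * blob.amplitude * g
    field[~mask] = 0.0
    inside = field[mask]
    inside = inside - inside.mean()
    norm = np.linalg.norm(inside)
    if norm == 0:
        raise ValueError("planted pattern is identically zero (all amplitudes 0?)")
    out = np.zeros_like(field)
    out[mask] = inside / norm
    return out


def _inside_mask(template: PhantomTemplate, point_mm: Triple) -> bool:
    idx = tuple(
        int(np.floor(p / s)) for p, s in zip(point_mm, template.spacing_mm)
    )
    if any(i < 0 or i >= n for i, n in zip(idx, template.grid_shape)):
        return False
    return bool(template.brain_mask[idx])


def simulate_cohort(
    template: PhantomTemplate, pattern: np.ndarray, config: CohortConfig
) -> SyntheticCohort:
    """Draw a control/patient cohort from the log-linear generative model.

    Controls come first (``z ~ N(0,1)``), then patients
    (``z ~ N(delta, tau^2)``).  Identical config (including seed) yields a
    bitwise-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    mask = template.brain_mask
    n_c, n_p = config.n_control, config.n_patient
    z = np.concatenate(
        [
            rng.normal(0.0, 1.0, size=n_c),
            rng.normal(config.delta, config.tau, size=n_p),
        ]
    )
    alpha = rng.normal(0.0, config.sigma_global, size=n_c + n_p)
    labels = ["control"] * n_c + ["patient"] * n_p
    ids = [f"ctl{i:03d}" for i in range(n_c)] + [f"pat{i:03d}" for i in range(n_p)]

    mu_in = template.mu[mask]
    p_in = pattern[mask]
    scans: list[Scan] = []
    for s in range(n_c + n_p):
        eps = rng.normal(0.0, config.sigma_noise, size=mu_in.shape)
        values = np.zeros(template.grid_shape, dtype=np.float64)
        values[mask] = np.exp(mu_in + alpha[s] + z[s] * p_in + eps)
        scans.append(
            Scan(values=values, spacing_mm=template.spacing_mm, id=ids[s])
        )
    return SyntheticCohort(
        scans=scans,
        labels=labels,
        true_scores=z,
        pattern_truth=pattern,
        template=template,
    )


def simulate_body_phantom(spec: LesionPhantomSpec) -> tuple[Scan, np.ndarray]:
    """Paint the phantom and return (SUV scan, truth label volume).

    Truth codes: 0 background, 1..K lesions (in spec order), -1..-M organs.
    Overlapping lesions are rejected so the ground truth stays unambiguous;
    organs may not overlap lesions either.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = spec.spacing_mm
    xs, ys, zs = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    extent = [n * s for n, s in zip(shape, spacing)]

    def membership(solid: Solid) -> np.ndarray:
        cx, cy, cz = solid.center_mm
        ax, ay, az = solid.size_mm
        for c, a, e in zip(solid.center_mm, solid.size_mm, extent):
            if c - a < 0 or c + a > e:
                raise ValueError(f"solid at {solid.center_mm} extends outside the grid")
        if solid.shape == "box":
            return (
                (np.abs(xs - cx) <= ax)
                & (np.abs(ys - cy) <= ay)
                & (np.abs(zs - cz) <= az)
            )
        return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + (
            (zs - cz) / az
        ) ** 2 <= 1.0

    values = np.full(shape, spec.background_suv, dtype=np.float64)
    truth = np.zeros(shape, dtype=np.int32)
    for k, lesion in enumerate(spec.lesions, start=1):
        member = membership(lesion)
        if (truth[member] != 0).any():
            raise ValueError("overlapping lesions: ground truth would be ambiguous")
        truth[member] = k
        values[member] = lesion.suv
    for m, organ in enumerate(spec.organs, start=1):
        member = membership(organ)
        if (truth[member] > 0).any():
            raise ValueError("organ overlaps a lesion: ground truth would be ambiguous")
        truth[member] = -m
        values[member] = organ.suv
    scan = Scan(values=values, spacing_mm=spacing, id="phantom", units="SUV")
    return scan, truth
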