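# Methods

## The model

`covpet` derives a *disease-related metabolic covariance pattern* from
FDG-PET brain scans of a control group and a patient group, and applies it
prospectively to single scans. The underlying statistical model is the
scaled subprofile model (SSM): after whole-brain intensity normalization,
the log intensity of subject *s* at voxel *v* is decomposed as

    log y_sv = mu_v + alpha_s + sum_k z_sk * p_kv + eps_sv

where `mu_v` is a shared mean log profile, `alpha_s` a subject-specific
global offset (the multiplicative scaling factor of the raw scan),
`p_k` spatial covariance patterns with subject expressions `z_sk`, and
`eps` residual noise. Removing each row's mean eliminates `alpha_s`
exactly; removing each column's mean across subjects isolates the *group
mean profile* (GMP) and leaves the *subject residual profiles* (SRP). PCA
of the SRP matrix recovers the covariance patterns; a linear combination
of the leading components oriented to separate patients from controls is
the disease-related pattern (a unit-norm voxel weight map).

Expression of the pattern in any scan — derivation subject or new — is
the inner product of the weights with that scan's residual profile
(log-normalized, own-mean-centered, GMP-subtracted): the topographic
profile rating. Because prospective scoring repeats the derivation
bookkeeping operation for operation, forward-scoring a derivation subject
reproduces its derivation score to round-off; the suite pins this at
1e-10. Scores are invariant to multiplying a scan by any positive
constant, which is what makes them usable on non-quantitative PET.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fwhm_mm` | 10 | isotropic Gaussian smoothing FWHM before analysis (mm) |
| `mask_fraction` | 0.2 | data-driven brain mask: voxel kept iff above this fraction of each scan's positive-voxel mean, in every scan |
| `vaf_cutoff` | 0.5 | candidate components = smallest prefix of PCs whose cumulative variance fraction reaches this |
| `z_convention` | `control` | Z-reference: control raw-score mean/SD (controls get Z mean 0, SD 1 exactly) or `pooled` (whole derivation sample) |
| `fraction` | 0.41 | lesion isocontour threshold as a fraction of each lesion's SUVmax |
| `min_suv` | 2.5 | minimum SUV for an automatic lesion peak |

Component selection and combination are genuinely open design choices
(published pattern-derivation practice varies): this package takes the
cumulative-VAF prefix and combines components with the Fisher linear
discriminant of the group labels in component-score space (pooled
within-group covariance, ridge 1e-8). Both knobs are arguments, not
constants. The sign convention — patients express the pattern more than
controls — and the deterministic eigenvector sign rule (largest-magnitude
loading coefficient positive) make derivations reproducible bit for bit.

The two Z conventions exist because a control-referenced Z forces the
control SD to 1, while published group summaries sometimes show a control
SD well below 1, implying a pooled-sample reference. Both are
implemented; control-referenced is the default; the choice is recorded in
the pattern sidecar.

## What the synthetic generator does and does not emulate

`covpet.synthetic` draws cohorts directly from the log-linear model above
with a single planted pattern: an ellipsoidal "brain" with a gray-shell /
white-core mean profile, a blob pattern with bilateral positive foci in
inferior/central structures and negative foci in posterior/superior
cortex, subject expressions `z ~ N(0,1)` for controls and `N(delta,
tau^2)` for patients, global offsets `alpha ~ N(0, sigma_global^2)` and
i.i.d. voxel log-noise. Defaults: 49 controls, 64 patients, `delta=1.3`,
`tau=0.9` (echoing a patient Z distribution of roughly 1.3 ± 0.9),
`sigma_noise=0.02` — set so the per-voxel RMS pattern signal
(`sqrt(delta^2+tau^2)/sqrt(V)` ≈ 0.009 at V ≈ 30k masked voxels) is about
half the voxel noise SD, i.e. per-voxel SNR ≈ 0.5 before smoothing.

Because the generator *is* the model the estimator assumes, recovery
tests demonstrate correctness of the implementation, not robustness to
real data: no anatomy, no partial-volume effects, no scanner noise
correlation, no registration error, and a single planted component rather
than a mixture. The same caveat applies to the body phantoms: lesions are
constant-SUV ellipsoids/boxes with voxel-center membership, which makes
TMTV ground truth an exact count and the 41% isocontour trivially correct
when the background is below 41% of lesion SUV — by design, so the
segmentation bookkeeping can be verified exactly.

Post-treatment scans in the demo pipeline are an *independent* patient
redraw at the post-treatment expression distribution (`delta=0.9`,
`tau=0.78`); within-subject correlation of baseline and post expression is
not modeled, so paired-test power on synthetic data understates what
longitudinal data would give.

## Numerical choices

- Smoothing uses renormalized convolution (filter the volume and an
  all-ones volume with zero padding, divide) so constants are preserved
  and mask-edge voxels average in-grid data only; sigma per axis is
  `fwhm / (2 sqrt(2 ln 2)) / spacing`.
- Log transform floors values at 1e-6 of the masked mean and warns,
  rather than erroring, because smoothed phantom edges can underflow.
- Voxel vectors are linearized in C order; the mask fingerprint (SHA-1 of
  shape, spacing and membership) is stored with the pattern and checked
  before scoring — mismatched grids error instead of resampling.
- PCA runs as thin SVD of the SRP matrix (subject-space cost); tests
  verify equality with the voxel-space eigendecomposition at 1e-8 and
  full-component reconstruction at 1e-6. Numerically null directions
  (singular value < 1e-10 of the largest) are dropped; double-centering
  always kills at least one.
- Lesion peaks on constant-SUV plateaus are reduced to one representative
  (nearest the plateau centroid, lexicographic tie-break); overlapping
  isocontour regions merge into the higher-peak lesion; final labels sort
  by peak SUV then coordinate. After a merge, voxels contributed by the
  absorbed peak satisfy the 41% rule relative to that peak, not
  necessarily the merged lesion's higher peak; disjoint-lesion phantoms
  (where the guarantee is exact) are what the tests pin.
- Mann-Whitney switches from exact enumeration to the tie-corrected
  normal approximation above combined n = 20 or in the presence of ties;
  identical constant groups return p = 1 with a degeneracy flag.
- Steiger's dependent-correlation Z uses the pooled-correlation variant
  (`rbar = (r_xy + r_xz)/2`) of the Fisher-z statistic; its null
  calibration is checked by Monte Carlo (10^4 trivariate-normal draws,
  size 0.05 ± 0.015).
- Dunn's post hoc adjustment is Bonferroni over the three pairs.

## Problem sizes

The routine suite runs on 32x32x24 grids at 4 mm spacing (same physical
extent as the full-resolution setting) with reduced cohorts; the
acceptance checks run ten full cohorts (49/64 subjects, 64x64x48 voxels
at 2 mm) — the scale at which pattern recovery (|r| ≥ 0.9 against the
planted truth, 10/10 seeds) is asserted.

## Known limitations

Spatial normalization/registration, SUV calibration from DICOM, manual
VOI editing, response-scale scoring and survival analysis are out of
scope. The automatic peak detector replaces manual lesion seeding;
explicit seed coordinates can be supplied to mimic semi-automatic
workflows. Exclusion masks are applied exactly as given — the package
does not decide which physiological uptake to exclude.
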