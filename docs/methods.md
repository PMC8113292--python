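# Methods

## Data model and conventions

Volumes are 3-D grids in SUV units (g/ml) with per-axis spacing and an
axis-aligned affine; voxel values represent voxel centres.  Axis 2 is
superior–inferior ("axial slice" = fixed index on axis 2), axis 0 is
left–right, so the sagittal stack used for the MRI-style reference runs
along axis 0.  Ground-truth labels use 0 = background, 1 = tumour
(including any necrotic core), 2 = bladder, 3 = other physiologic
structure (bowel, ureter).  All masks are stored as uint8 NIfTI-1.

## Reference volume

The reference standard emulates how a radiologist measures cervical
tumour volume on sagittal T2-weighted MRI: one cross-sectional area is
contoured per 5-mm slice and the per-slice volumes (area × thickness)
are summed.  `reference_mri_volume` aggregates native slices into slabs
whose representative area is taken from the central native slice(s) — a
midpoint rule.  This choice is exact for slabs aligned with slice
boundaries, reduces to plain voxel summation when the thickness equals
the native spacing, and carries ≈0.5% error on a 26-mm sphere
rasterised at 1 mm; aggregating by majority vote instead biases convex
shapes outward by ~3%, which is why it was not used.  Because the PET
grid is 3-mm isotropic (5 mm is not an integer multiple), the pipeline
computes the reference on a 1.25-mm rasterisation of the analytic
ground-truth tumour, standing in for the higher-resolution MRI frame.
Necrotic interiors carry the tumour label and are therefore included,
as in the clinical measurement convention.

## Segmentation methods

**Fractional thresholding (method 1).**  SUVmax is the maximum of the
(bladder-masked, exclusion-applied) image within a 60-mm sphere around
the seed; the VOI is the 26-connected component of
{SUV ≥ fraction·SUVmax} containing the seed.  Fractional thresholds are
inclusive (≥), so fraction 1.0 retains the maximum voxel; the fixed
absolute rule is strict (SUV > 2.5), matching how it is conventionally
written.  26-connectivity is the common PET-VOI convention and is what
the brute-force flood-fill oracle in the tests uses.  A `connected=False`
switch yields the plain intensity cut within the search sphere, since it
is unknown whether clinical tools connectivity-limit their `%SUVmax`
VOIs.

**Bladder masking.**  Masking is *decided* on the plain intensity cut
within the search sphere — the auto-contour a clinical tool displays —
using the rule: bladder outlined instead of tumour (> 50% of trial
voxels in bladder; the quantitative cut is our operationalisation) or
bladder included on > 5 axial slices.  Deciding on the connected
component instead fails in an important scenario: a hot bladder can
inflate SUVmax without ever entering the tumour's component, so masking
would never trigger while every threshold is referenced to the wrong
maximum.  The *masked image* zeroes the bladder label dilated by 6 mm
(≈ the PSF width): a masking tool outlines the bladder's blurred
appearance, and zeroing only the anatomical label would leave a hot
spill ring that dominates the subsequent SUVmax search for low-uptake
tumours.  Masking is decided per threshold, since the trial contour
(and hence the need) depends on the threshold.

**Adjustment surrogate.**  Human editing is replaced by removing mask
voxels that carry non-tumour labels, graded by the number of axial
slices affected (none / ≤ 5 / 6–20 / ≥ 21 = not measured).  Background
spill is deliberately *not* removed — editors remove identifiable
organs, not faint background, which is why the fixed SUV 2.5 cut keeps
its characteristic overestimation after adjustment.  Removal may split
a component; the split is recorded, not repaired.

**Ellipsoid constraint (method 2).**  An axis-aligned ellipsoid
restricts both the SUVmax search and the thresholded set; the VOI is
the in-ellipsoid connected component containing the in-ellipsoid
maximum voxel.  The fixed SUV 2.5 rule is also run under this
constraint.  No editing is possible afterwards, mirroring the clinical
software behaviour.

**Radial-gradient method (method 3).**  From the centroid of the
connected near-peak region (flat-topped blurred peaks otherwise give
seed-dependent ray origins), 200 quasi-uniform rays (golden-spiral
sampling) are cast; profiles are sampled by trilinear interpolation at
0.5-voxel steps and smoothed with a 0.5-voxel-σ Gaussian; each ray's
boundary is the arg-max of |d(SUV)/dr| beyond the profile peak, with
parabolic sub-sample refinement.  Two safeguards implement edge
continuity: the per-ray search stops where the profile rebounds by more
than 10% of its descent (the valley before an adjacent hot structure,
so a neighbour's edge is not taken), and every radius is twice replaced
by the median over its 8 nearest directions.  For a blurred convex
boundary the derivative peak sits inward of the true edge by ≈ σ²/r (a
partial-volume curvature effect, exact to first order for Gaussian
blur); radii are compensated using the protocol-known reconstruction
PSF (5 mm FWHM default) plus the profile-smoothing width.  With the
compensation, noiseless blurred spheres of radius 15–30 mm are
recovered within ±3.5% in volume.  The VOI is the voxel set inside the
resulting star-shaped surface (nearest-ray lookup); non-star-shaped
lesions are therefore truncated, one reason the method underestimates
irregular tumours.

**Seeding.**  The simulated reader's click is placed at the tumour
centre; before segmenting, the pipeline snaps it to the hottest voxel
within 40 mm (peak locking, as clinical tools do), and if the snapped
anchor still falls below the threshold — possible when a hotter
structure inflates SUVmax — the anchor falls back to the SUVmax voxel
of the search sphere.  This is required because necrotic phantoms place
the geometric centre in a cold core.

## Statistics

ICC(2,1) is computed from the two-way ANOVA mean squares,
(MSR − MSE)/(MSR + (k−1)·MSE + k(MSC − MSE)/n), with exact F-based 95%
bounds in the McGraw–Wong convention (the model named by the analysis;
the CI construction is our choice, as none is specified by the
convention's common usage).  Degenerate inputs are defined rather than
fatal: duplicated readers give ICC = 1 with CI (1, 1); identical
readings across cases raise, since no between-case variance exists.
Reliability bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
> 0.9 excellent.  Pearson bands on |r|: < 0.1 none, 0.1–0.29 small,
0.3–0.49 medium, ≥ 0.5 large.  The paired t test returns p = 1 for
identical samples and p = 0 with a point CI for constant non-zero
differences.  Percentage difference is the mean of per-case ratios,
100·(MTV−ref)/ref, not the ratio of means.  Bland–Altman uses
d = x − y against m = (x+y)/2 with limits bias ± 1.96·sd(d);
proportional bias is the regression-slope t test of d on m at α = 0.05
(the phenomenon's standard test).  Unmeasured cases are dropped
pairwise per row with the drop count reported; rows with n < 3 (or
< 5 complete pairs for ICC) carry absent statistics rather than
raising.  The independent-samples comparison option defaults to Welch
variances.

## Synthetic cohort

`CohortSpec` defaults encode the study population: log-normal volumes
fitted to mean 85.4 ml / SD 69.8 ml, truncated to [5, 450] ml (the 5-ml
floor is the small-lesion exclusion); truncated-normal SUVmax
15.1 ± 6.9 with floor 3; necrosis in 35/81 of tumours with core
fraction 0.25–0.55 of the radius and necrosis SUV 1.0–2.5; lobulation
amplitude 0.05–0.25 (cervical tumours are irregular rather than
ellipsoidal); bladder SUV uniform on [8, 30] so urinary activity
frequently exceeds the tumour threshold levels; tumour–bladder gap
6 mm; grid 96³ at 3 mm; PSF 5 mm FWHM; additive Gaussian SUV noise
σ = 0.5 (no count-level data exist, so post-reconstruction Gaussian
noise is the desk-scale surrogate).  Background SUV 1.5 is our choice;
no tumour-to-background statistics are published for this population.
Lobulation is a degree-2 solid-harmonic modulation of the ellipsoid
radius, normalised so the amplitude is the peak fractional
perturbation.

Label-3 structures are part of the default cohort: four distant bowel
loops, one per superior–inferior stratum with uptake 2.6–4.5, so that
a contour which floods the soft-tissue background (threshold at or
below the noisy background level) sweeps them up across well over 20
axial slices and is graded too difficult — the run-away failure mode of
very low thresholds on low-uptake tumours; a urine-hot ureter segment
lateral to the tumour in 60% of cases and a mildly avid pericervical
bowel loop in 40%, which low-threshold contours bridge into and which
drive the major-adjustment burden.

Reader simulation: reader 1 clicks the tumour centre and draws the
bounding ellipsoid with a 30% margin, capped toward every adjacent
structure at 60% of the surface gap (observers avoid adjacent
physiologic structures); reader 2 receives a click jittered within
±2 mm (constrained to stay inside the tumour) and 5% fractional jitter
of the ellipsoid.  This perturbation is the only source of
inter-reader variance.  Per-case seeds derive deterministically from
the master seed; identical configuration and seed give byte-identical
outputs.

## What the phantoms do and do not emulate

They emulate the geometry that makes this problem hard — an abutting
high-uptake bladder, adjacent urine-hot and mildly avid structures,
reconstruction blur, noise, necrosis, irregular shape — and the cohort
distributions of volume and uptake.  They do not emulate sinogram-level
physics (scatter, randoms, spatially varying resolution), respiratory
or bladder-filling motion, body outline and air, spatially correlated
noise, or true human editing behaviour.  Consequences to keep in mind
when reading the outputs: measured SUVmax runs ≈10% above the
generative parameter because the hottest-voxel statistic rides on the
noise maximum; simulated readers agree far more closely than humans
(ICCs cluster near 1, so the analysis demonstrates the machinery and
the ordering of effects, not realistic inter-observer spread); fine
minor-grade (1–5 slice) adjustments are under-represented because
structure inclusion here tends to be all-or-nothing; and gradient-method
bladder masking is needed more often than clinically reported because
nearly every phantom places the bladder directly against the tumour.
Passing tests therefore establish correctness of the measurement and
statistical machinery under the stated generative model, not clinical
performance.

## Problem sizes and runtimes

Default experiments use 50 cases at 96³ voxels — about two minutes on
one CPU for the full two-reader, three-method, eight-threshold run.
Unit tests use 8³ grids for oracle equivalence (exhaustive enumeration
stays trivial), 64–65³ grids for single-phantom checks, and 200-case
spec-only draws for distribution checks.

## Known limitations

The ellipsoid constraint is axis-aligned; oblique ellipsoids are not
supported.  The gradient surface is star-shaped by construction.
DICOM ingestion, SUV decay computation, image registration, partial
volume correction and DICE overlap between modalities are out of scope.
The grading surrogate sees only labelled structures, so editing effort
against unlabelled background is invisible to it by design.
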