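# Methods

## The measurement model

Dual-phase CT hepatic arteriography produces, per session, a native
(non-contrast) volume `N` and an arterial volume `A` in Hounsfield units on
a quasi-isotropic high-resolution grid (0.6 mm voxels by default). Between
the two acquisitions the liver moves slightly (breathing, catheter
manipulation), so true enhancement is defined through a voxel-level
mapping: a dense displacement field `u` on the arterial grid with
`p_moving = p + u(p)` (world mm, LPS-style axes, 0-based indices, voxel
centers). The enhancement map is

    EM(p) = A(p) − N(p + u(p)),

signed, unsmoothed and unclipped. Negative and near-zero values are
informative: contrast stasis after embolization is bright in *both* phases
and subtracts to a void, which is exactly the confound the method removes.
Out-of-field samples become NaN and are excluded from every statistic.

## Registration

**Deformable (within session).** Multiresolution (shrink factors 4/2/1,
default 150/80/20 iterations) symmetric-forces demons, with displacement-
and update-field Gaussian regularisation of σ = 2 voxels. Demons assumes
intensity constancy, which arterial enhancement violates; two
normalisations make the pair quasi-constant:

* HU clipping to [−100, 200] suppresses arterial-only vessels;
* histogram matching of the native onto the arterial intensity
  distribution removes the parenchymal enhancement offset, which otherwise
  drags the match along texture gradients (on default phantoms this step
  alone moves the mean recovery error from ≈ 1.9 mm to ≈ 1.0 mm).

The report carries the per-level metric trace; `converged` means the final
metric of each level does not exceed its first. Demons metric sequences
are not guaranteed monotone under noise, so monotonicity is not asserted
beyond that. Accuracy contract (checked on the seeded phantom suite): mean
displacement-recovery error inside the liver ≤ 1.3 mm at 5 mm deformation
amplitude; measured ≈ 1.0–1.2 mm.

**Rigid (between sessions).** The pre- and post-treatment maps are
co-registered with a mean-squares Euler3D registration and the post map is
resampled onto the pre grid. The anchor images are the *arterial* volumes:
the maps live on arterial geometry, and each session's native phase
carries its own intra-session deformation — rigidly registering the native
volumes fits that (real, non-rigid) motion and produced gross spurious
transforms (~9°) on phantoms. Rigid rather than deformable by default so
genuine enhancement differences are not deformed away; anchors are
configurable, including the maps themselves.

## The relative-enhancement statistic

* `ROI_tumor`: the tumor cross-section on the axial or coronal slice of
  maximal in-plane area (ties → axial). Tumor masks are inputs (phantom
  truth, or user-drawn); automatic segmentation is out of scope.
* `ROI_normal`: a circle of 300 mm² (default) of vessel-free parenchyma in
  the contralateral lobe, centered at the point maximising in-plane
  distance to vessels, the liver boundary and the lobe split plane.
  Laterality is decided by the tumor centroid's x relative to a supplied
  split plane; full hepatic lobe segmentation is out of scope.
* `T_RE = mean(EM | ROI_tumor) / mean(EM | ROI_normal)`; residual iff
  `T_post_RE > 1` (1.0 exactly is non-residual).
* High-attenuation correction (post-treatment only): the tumor mean uses
  voxels with `EM > τ`, default τ = 0 ΔHU — zero exactly excludes stasis
  subtraction voids. If no voxel qualifies, the whole-ROI mean is used and
  the mode is flagged inapplicable. τ, the ROI area, and the tie rule are
  parameters the underlying method leaves open; all are recorded in every
  report.

ROIs are stored as polygons in world mm. Tumor outlines are traced at the
0.5 level between pixel centers, so rasterisation (point-in-polygon at
voxel centers) reproduces the source pixel set exactly; a regular-128-gon
whose shoelace area equals the requested area stands in for the circle.

## Feeder identification

The underlying method reads 5–10 mm thin-slab MIPs by eye; this package
substitutes an explicit surrogate so the judgement is reproducible:

1. residual regions = 26-connected components of tumor voxels with
   `EM > 20 ΔHU` (≈ the parenchymal uplift; configurable), ≥ 5 voxels;
2. multiscale Frangi vesselness (scales 0.9/1.5/2.4 mm), normalised to
   [0, 1];
3. minimal-cost path from the hepatic-artery root (an input) to the region
   over step cost `length × 1/(v + 10⁻³)`, with vesselness re-normalised
   by its maximum so the path is invariant to uniform rescaling; a best
   path whose minimum vesselness is below 0.1 means "no artery leads to
   the region" (returns none);
4. persistent feeder vs new collateral: fraction of path points within
   1.2 mm of the pre-treatment vessel mask, threshold 0.5 (≥ rule).

Tracing runs in 3D on the full map; MIP slabs (default 7 mm, the midpoint
of the conventional 5–10 mm range) are rendered for QC only, avoiding
projection ambiguities. The parameters (threshold, ε, dilation, overlap)
are surrogates for a visual judgement and are reported in every output.

## Diagnostic evaluation

Positive class = residual enhancement / non-complete response (mRECIST PR
or SD); CR is negative. Sensitivity, specificity, PPV, NPV and accuracy
come with exact Clopper–Pearson 95% intervals (Beta quantiles; lo = 0 at
k = 0, hi = 1 at k = n). Clopper–Pearson reproduces the reference
sensitivity/specificity/accuracy intervals to the printed precision; the
reference PPV/NPV intervals match no single standard method we could
identify, so the summary labels `ci_method` explicitly and those two
bounds are not asserted anywhere. Group comparison uses the Wilcoxon
rank-sum test: exact two-sided p by enumeration of all C(n, n_a) mid-rank
assignments for n ≤ 20 (ties via mid-ranks), normal approximation with tie
correction above. p < 0.05 is reported as a significance flag, never used
as a filter.

## The phantom

`cthaem.phantom` generates complete synthetic cases: liver = ellipsoid
(HU 55 native) with smooth parenchymal texture (σ = 10 HU, ≈ 5 mm
correlation length, identical across phases — anatomy, not noise; real
parenchyma is heterogeneous, and a perfectly flat liver would make
interior deformation unobservable *in principle*, a phantom artifact
rather than a property of the modality); tumor = sphere (HU 45,
hypodense); arterial uplift 20 HU parenchyma / 60 HU tumor, so the
analytic `T_pre_RE` is 3.0; vessels = curved tubes with Gaussian
cross-section (peak 250 HU, arterial phases only, compact support at 3
radii), flagged pre-only / post-only / both.

Post-treatment construction for residual fraction `f`: the residual region
is a spherical cap at the tumor margin (`x ≥ x₀`, with x₀ chosen among
voxel-column midpoints to minimise |voxel fraction − f|; a binary plane
cut cannot hit f closer than about half a voxel column) keeping the full
60 HU uplift; the treated remainder receives +150 HU stasis in both
post-treatment phases (cancelling under subtraction) and no arterial
signal (the embolized bed). With τ = 0 the analytic post statistic is
`60/20 = 3` whenever `f > 0` and 0 at `f = 0`; at `f = 0.5` the whole-ROI
ratio is exactly 1.5 on the equatorial slice while the subset restores 3.0
— the correction case.

Acquisition effects: a smooth random deformation between native and
arterial phases (superposed Gaussian bumps, bandwidth ≥ 20 mm, rescaled to
the requested maximum amplitude, Jacobian checked positive; the native
phase is rendered through the numerically inverted field so the stored
truth is exactly what a perfect registration would recover), an optional
rigid shift between sessions, and independent additive Gaussian noise per
acquisition (default σ = 8 HU — a plausible abdominal CT value, chosen
once; the source data's noise statistics are unreported). Defaults: 96³
voxels at 0.6 mm, deformation amplitude 3 mm (5 mm in the registration
benchmark), prevalence 0.4 with residual fractions drawn from [0.2, 0.8]
in cohorts. Identical seeds give bit-identical cases.

What the phantom does **not** emulate: beam hardening, scatter, motion
artifacts, pharmacokinetics, real vessel anatomy, lesion heterogeneity,
and inter-patient variability. Passing phantom tests therefore shows the
*pipeline* is correct and robust at realistic contrast/noise/deformation
scales — not that clinical accuracy equals the phantom accuracy.

## Numerical choices and degenerate inputs

* Zero displacement on a matching grid short-circuits interpolation, so
  identity-field subtraction is bit-exact (and verified against a naive
  per-voxel loop).
* The analytic-recovery checks run the subtraction + ROI chain with the
  known (identity) field on noise-free phantoms: running an optimiser on
  an already-aligned pair with genuine enhancement differences produces
  sub-voxel jitter at contrast boundaries, which is a property of any
  intensity-driven registration, not of the statistic under test.
* Normal-ROI mean ≤ 0 raises a normalisation error (failed parenchymal
  enhancement or a misplaced ROI) rather than returning a sign-flipped
  ratio.
* A metric denominator of 0 (e.g. PPV with no positive calls) reports that
  metric as undefined and computes the rest.
* Degenerate MIP slabs (thinner than one spacing) take the single nearest
  slice; slabs outside the volume raise.
* Scaled-down problem sizes used in the validation suite (48³–64³ unit
  phantoms vs the 96³ benchmark suite, 20-case cohorts, 10-phantom feeder
  suites) were chosen as the smallest sizes at which the geometry still
  resembles the clinical setting.

## Known limitations

* The registration is an open re-implementation contracted by accuracy
  (≤ 1.3 mm mean recovery on phantoms), not an algorithmic copy of any
  vendor software.
* Feeder identification depends on an operator-supplied arterial root and
  on vesselness parameters tuned for tube radii near 1 mm.
* Lobe laterality is a plane split, not a segmentation.
* Planar-ROI operations require axis-aligned volume geometry; oblique
  acquisitions must be resampled first.
* No DICOM writing, gantry-tilted series, or 4D volumes.
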