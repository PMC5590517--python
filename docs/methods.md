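# Methods

`cordisp` implements, as a reusable and fully tested pipeline, the analysis
chain used to validate MRI-derived neurite orientation dispersion against
quantitative histology in post-mortem spinal cord — exercised here entirely
on a synthetic phantom with known ground truth, since no real specimen data
are distributed with the package.

## The diffusion model

Each voxel's diffusion-weighted signal is modelled as a mixture of four
water pools (the ex-vivo variant of the dispersed-stick, or NODDI, model):

    S(b, g) = s0 [ v_iso e^(-b d_iso)
                   + (1 - v_iso) ( v_ir + (1 - v_ir)( v_in A_in + (1 - v_in) A_en ) ) ]

* **Free water** (fraction `v_iso`, the IVF map): isotropic Gaussian
  diffusion with the diffusivity of the immersion buffer.  The paperless
  constant here is `d_iso = 2.0 um^2/ms` (phosphate-buffered saline at
  35 °C), exposed in every fitting configuration.
* **Isotropically restricted ("dot") water** (fraction `v_ir` of the
  non-free tissue signal): no attenuation at any b, a standard additional
  compartment for fixed ex-vivo tissue.  `A_dot = 1`; the nesting chosen
  here (a fraction of the non-free-water tissue signal) is one of several
  used in the ex-vivo literature and is asserted by the unit tests.
* **Intra-neurite water** (fraction `v_in` of the mobile tissue water, the
  NDI map): zero-radius cylinders ("sticks") with intrinsic diffusivity
  `d_par = 1.50 um^2/ms`, orientations Watson-distributed with
  concentration `kappa` about the mean axis `mu`.
* **Extra-neurite water**: an anisotropic Gaussian tensor with tortuosity
  `d_perp = d_par (1 - v_in)`, orientation-averaged under the same Watson
  distribution (i.e. the *tensor* is averaged, then exponentiated).

Dispersion is reported as `ODI = (2/pi) arctan(1/kappa)`: 0 for perfectly
parallel neurites, 1 for isotropic orientations.

### Numerical evaluation of the Watson averages

The intra-neurite average `A_in = E[exp(-b d_par (g.n)^2)]` is an integral
of `exp(n^T B n)` over the sphere with `B = kappa mu mu^T - b d_par g g^T`.
`B` is a rank-2 matrix whose eigenvalues have closed form; taking the polar
axis along the smallest eigenvalue, the azimuthal integral is
`2 pi exp(s m) I0(s d)` and the remaining 1-D integral is evaluated with a
fixed 128-point Gauss–Legendre rule (exponentially scaled Bessel `i0e` for
overflow safety).  The Watson normalizer is computed with the *same* rule,
so `S(b=0) = s0` holds bit-exactly and quadrature errors largely cancel.
Against a 10,000-point brute-force spherical quadrature
(`cordisp.reference`), the maximum relative error over the acquisition
protocol and a wide parameter grid is ~1e-13 — far below the 1e-4 level the
package guarantees.  The rule is accurate for `kappa <= ~130` and
`b d_par <= ~30` (the fitting bounds and the protocol stay well inside);
`kappa = inf` is handled exactly as the parallel-stick limit.

### Fitting

`fit_noddi` estimates `s0` from the mean b=0 signal, normalizes, then per
voxel:

1. a coarse dictionary search over `(v_iso, v_ir, v_in, ODI)` (vectorized
   across voxels, ~2000 atoms) with the neurite axis fixed to the principal
   eigenvector of a diffusion-tensor fit — exact for noise-free data by the
   model's cylindrical symmetry;
2. Levenberg–Marquardt refinement in transformed coordinates (logistic for
   the three fractions, log for `kappa`, spherical angles for `mu`), with a
   Gaussian least-squares objective.  A Rician maximum-likelihood objective
   is available behind a flag (`objective="rician"`, requires the noise
   sigma) but is not the default.

The axis sign is fixed by hemisphere convention (z >= 0, ties broken toward
y >= 0 then x >= 0).  All fits are deterministic: the dictionary has no
random jitter and the refinement is initialized from the grid optimum.
Voxels with non-positive mean b=0 are flagged `converged = -1` and skipped.
On noise-free signals the fit recovers generating parameters to ~1e-6
(asserted at 1e-3 over a 3^4 grid) and attains objective < 1e-10.

### DTI

`fit_dti` uses weighted linear least squares on `ln S` (weights = squared
observed signals) restricted to the Gaussian regime `b <= 4680 s/mm^2`;
measurements above that shell provably do not influence the result.
AD/RD/MD come from the eigenvalues, FA from the standard normalized
eigenvalue-dispersion formula computed on the *raw* eigenvalues (negative
eigenvalues raise a QC flag rather than being clamped; only the FA map
output is clipped to [0, 1]).  Non-positive signals are excluded per voxel
with a logged warning; a voxel left with fewer than 7 usable measurements
is reported NaN.

## The acquisition protocol

`default_protocol()` reproduces the six-shell ex-vivo scheme used
throughout: 25 b=0 measurements plus shells at b = 520, 2080, 4680, 8320,
13000, 18720 s/mm^2 with 6, 15, 24, 33, 42, 51 directions (196 total).
Directions are spread per shell by electrostatic repulsion with antipodal
symmetry from a fixed seed, so the protocol is identical across runs.
Timing metadata (delta/Delta = 12/18 ms, TE/TR) is stored but unused by the
models, which are b-value/direction models only — gradient-timing-dependent
restricted diffusion is out of scope.

## Histology quantification

Images are processed at their native pixel size (1.008 um/px is the default
of the image container, matching slide-scanner resolution).

* **Neurite segmentation**: 1-D k-means (k = 4, k-means++ with 20 restarts,
  fixed seed, predictions by centroid midpoints so few-tone images are
  exact) on intensity within the tissue mask; the darkest cluster is the
  neurite (silver) class.  A constant tissue intensity is resolved against
  the out-of-mask background: uniformly dark tissue (intensity below half
  the background) is fully stained, otherwise the mask is empty.
  Immunostains use the same machinery with k = 3.
* **Orientations**: structure-tensor analysis — derivative-of-Gaussian
  gradients of spread `sigma_d` (default 1 um), Gaussian smoothing of the
  tensor components with `sigma_s` (default 4 um; the smoothing scale is a
  package choice exposed in the configuration).  The along-structure
  orientation is the eigenvector of the smaller eigenvalue; the confidence
  weight is the coherence `(l1 - l2)/(l1 + l2)`, zeroed where the tensor
  energy is below 1e-3 of its maximum.  Kernels below half a pixel are
  rejected as unresolvable.
* **Patch statistics**: patches tile the physical frame at the MRI in-plane
  resolution (0.16 x 0.20 mm^2), pixels assigned by center.  Dispersion per
  patch is the coherence-weighted axial circular variance
  `CV = 1 - |sum w e^(2 i theta)| / sum w` over neurite pixels — the
  operational reading of a weighted-Watson dispersion estimate on axial
  data; CV is exactly invariant to uniform weight rescaling and lives in
  [0, 1].  Patches with fewer than 50 contributing neurite pixels, or less
  than 50 % tissue coverage, are masked invalid (both thresholds stabilize
  CV in sparse patches and are configurable).  Staining fractions are
  stained-pixel counts over tissue pixels per patch.

## Registration

Histology-to-MRI co-registration is landmark-guided: a 2-D thin-plate
spline (kernel `r^2 log r`) solved from the standard augmented system, with
optional regularization `lambda` added to the kernel block (`lambda = 0`
interpolates landmarks exactly; the TPS reproduces affine maps with zero
kernel energy).  The exact TPS inverse has no closed form; the inverse used
for pull-back resampling is a refit with source and target swapped, whose
round-trip error is second order in the deformation (< 0.05 mm median for
landmark perturbations up to ~0.2 mm on a centimeter-scale frame).  Metric
maps are resampled bilinearly, masks by nearest neighbour; validity is
propagated and pixels mapping outside the source domain are invalid.
`register_with_qc` scans a small `lambda` grid {0, 0.001, 0.01, 0.1} and
keeps the warp maximizing the Dice overlap of the tissue outlines,
flagging results below Dice 0.5.  Outlines are extracted by Otsu threshold,
largest connected component, holes filled.

## ROI statistics

ROI medians of co-registered maps are extracted per metric; histology
metrics from two sections per MRI slice are averaged at the ROI-median
level (median within section, then mean across sections).  Pearson
correlations between each MRI metric (IVF, NDI, ODI, FA, AD, RD, MD) and
each histology metric (CV, MSF, NSF, ASF, uGSF) are computed within each
group separately, with two-sided t-tests on n-2 degrees of freedom and no
multiple-testing correction (per-test alpha 0.05).  Five regression models
relate each MRI metric to histological predictors (all five; CV+MSF+NSF;
CV+NSF; MSF+NSF; ASF+uGSF).  "Standardized beta" is OLS on the z-scored
response *and* predictors, standardized within the analysed group — chosen
so the single-predictor beta equals the Pearson r of the pair exactly
(asserted to 1e-10).  Zero-variance predictors are dropped with a flag;
condition numbers above 1e10 flag the result without aborting.

## The synthetic phantom

The phantom emulates a sagittal cord slab: 64 x 64 MRI voxels of
0.16 x 0.20 mm^2 containing an elliptical cord with a central gray-matter
column, white matter around it, and (in the "MS" variant) four focal
lesions punched out of each tissue.  Regional ground truth (chosen once as
field-typical values): WM ODI 0.10 / NDI 0.65 / IVF 0.05, GM ODI 0.45 /
NDI 0.45, WM lesions ODI 0.06 / NDI 0.30 / IVF 0.18 with MSF collapsing
from 0.55 to 0.10, GM lesions analogous — encoding the contrasts the
analysis must detect: higher dispersion in gray matter than white, lower
dispersion and myelin inside demyelinated lesions, higher free water in
lesions.  Each tissue is subdivided along the cord axis into ROIs (10 per
nonlesional tissue, one per lesion), giving 20 control and 28 MS ROIs
(N = 48); each ROI's true values receive 10 % relative multiplicative
jitter so ROI-level statistics have genuine between-ROI variance.

From the ground truth the generator produces:

* **DWI**: the forward model per ROI plus Rician noise (magnitude of a
  complex Gaussian perturbation, `sigma = s0/SNR`, default SNR 30 at b=0;
  infinite SNR returns the noise-free signal bit-exactly).  The
  second-moment identity `E[S^2] = S_true^2 + 2 sigma^2` is asserted by
  tests.
* **Fiber images**: dark strokes (~100 um long, two-tone ink) on a bright
  background; stroke axial orientations are drawn from the circular Watson
  distribution — after angle doubling, a von Mises with concentration
  `kappa/2` — using the *same* `kappa(ODI)` mapping as the 3-D model.  The
  2-D/3-D correspondence is monotone, not an identity, and the pipeline
  relies only on rank agreement between ODI and CV.  Stroke count scales
  with NDI.
* **Stain images**: dark disks from a seeded Boolean process whose
  intensity `-ln(1-f)/(disk area)` makes the expected covered fraction per
  ROI equal the true staining fraction; centers are sampled over the ROI
  dilated by the disk radius and clipped to it, so coverage is unbiased up
  to the boundary.  Realized fractions are within ±0.01 on megapixel
  regions.

The default pipeline renders histology at 4 um/pixel rather than 1.008 um:
strokes and blobs are a few pixels wide at any resolution, and 4 um keeps a
full-slab section at ~8 Mpx instead of ~130 Mpx, which is what makes the
two-specimen, twenty-section study run in minutes.  The structure-tensor
`sigma_d` follows the pixel size (1 px) in that regime.  Consequences: the
absolute CV scale measured on rendered strokes is compressed relative to
the generating circular variance (orientation smoothing and stroke overlap
shrink the weighted angle distribution toward the local mean), which is why
validation asserts monotone/rank recovery of dispersion, not CV value
matching.

What the phantom does *not* simulate: staining chemistry and color (images
are grayscale), section-thickness variation, air-bubble artifacts,
nonspecific staining, fixation effects, 3-D sectioning geometry.  Passing
tests therefore demonstrate the correctness of the computational chain
under the stated generative model, not robustness to those real-data
confounds; the optional tissue-mask input is the hook for excluding
artifact regions in real material.

## The end-to-end study

`run_full_analysis` simulates a control and an MS specimen, fits both
models, quantifies two histology sections per stain per slice in a
deliberately misaligned frame (3° rotation, 3 % scale, ~2 % shift of the
slab extent), registers patch maps back onto the MRI grid via 12 cord-
outline landmarks with Dice QC, extracts the 48-ROI metric table and runs
the correlation/regression battery per group.  A single seed fans out to
stage seeds via `numpy.random.SeedSequence.spawn` in fixed order; reports
are written with sorted keys so identical runs are byte-identical.  With
default sizes the study takes ~7 minutes on one CPU; the fitting effort
knobs (`max_nfev`, `refine_mu`) and phantom sizes trade accuracy against
time and are recorded in the report for provenance.

Known limitations: the dot fraction `v_ir` and free-water fraction can
trade off weakly at low SNR; the 2-D histology frame is a single section
pair rather than a through-slice average; lesion ROIs are small (tens of
voxels) so their medians are noisier than nonlesional ones; the registration
family is TPS only (no diffeomorphic or intensity-driven refinement).
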