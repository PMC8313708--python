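# Methods

This note documents the models, numerical choices and limitations behind
`bps-neuronav`, a vascular brain positioning system (BPS) for functional
ultrasound (fUS): the package registers a subject's 3D Power Doppler volume to
a pre-aligned Doppler reference, carries atlas labels into the live imaging
frame, targets probe planes, quantifies residual misalignment with ultrasound
localization microscopy (ULM), and runs task-evoked and resting-state
functional analysis. Everything is exercisable end-to-end on synthetic
vascular phantoms that return their own ground truth.

## Coordinate conventions

All world coordinates are millimetres in the stereotaxic frame: x lateral
(left→right), y antero-posterior with Bregma at 0 and posterior negative,
z depth positive downward. Voxel indices are 0-based; the world position of
voxel *i* is `origin + i·spacing` (voxel centres). Affine transforms store a
3×3 linear part, a translation and a rotation centre and act as
`L(p−c)+c+t`; `register_affine` returns the map taking moving-space points
into fixed space, and resampling pulls intensities through the inverse map.

## Doppler processing

A compounded frame ensemble (space × time) is clutter-filtered by singular
value decomposition of its Casorati matrix (rows = flattened space,
x-fastest; columns = time; singular values sorted descending): the
`cutoff_rank` largest components — slow, spatially coherent tissue motion —
are zeroed and the stack reconstructed. Power Doppler is the per-pixel
temporal mean of squared magnitude of the filtered stack. The energy of the
removed and kept parts sums to the input energy (orthogonality), and
filtering twice composes: truncating a then b components equals truncating
a+b at once.

The cutoff rank is exposed as a parameter with default 30% of the block
length (60 of 200 frames), a conventional operating point for rodent fUS
clutter rejection; no single value suits all motion regimes.

Acquisition arithmetic is held in two helpers: compound rate = PRF / number
of plane-wave angles (5500 Hz / 11 → 500 Hz), Doppler rate = compound rate /
block length (500 Hz / 200 frames → 2.5 Hz, 400 ms blocks). Volumes are
assembled from ordered coronal slices, first slice most anterior, elevation
spacing equal to the motor step (31 slices at 0.2 mm → a 6 mm
antero-posterior range).

Before registration, volumes are log-compressed (`log1p`), clipped to the
(1, 99) intensity percentiles and rescaled to [0, 1]. The mutual-information
metric is histogram-based; without log compression the heavy-tailed Doppler
intensity distribution collapses into a few bins.

## Registration

**Metric.** Mattes mutual information on a 50×50-bin joint histogram, all
fixed-volume voxels sampled (no stochastic subsampling by default). Bin
coordinates place each volume's min/max at the centres of the end bins
(half-bin padding). The fixed axis uses a box kernel (hard binning); the
moving axis uses a cubic B-spline Parzen window rescaled to one-bin support,
so an intensity exactly at a bin centre contributes to that bin alone and
off-centre intensities spread smoothly over the two adjacent bins. This
narrow kernel keeps the estimator consistent with a plain joint-histogram
count on bin-quantized data (self-MI of a volume occupying all 50 bins
equals ln 50) while still smoothing the metric between bins; the textbook
4-bin-support kernel trades that consistency for heavier smoothing
(≈0.9 nats lower self-MI) without helping a derivative-free optimizer.
Candidate transforms whose overlap with the fixed support drops below 10%
score −∞ (inside the optimizer) or raise (at the API), which stops the
search from escaping the brain.

**Parameterization.** 12 parameters — 3 intrinsic rotations (radians),
3 log-scales, 3 shears, 3 translations (mm) — composed as
`Rz·Ry·Rx·S·H`, rotation centre at the fixed-volume centroid. Per-parameter
optimizer scales condition the search (a unit optimizer step ≈ 1 mm of
translation ≈ 0.1 rad of rotation, i.e. 1 rad ≈ 10 mm of motion at brain
scale).

**Optimizer.** A (1+1) evolution strategy: perturb the current best by an
isotropic Gaussian scaled per-parameter, accept only improvements, grow the
radius by 1.05 on success and shrink by 1.05^(−1/4) on failure; stop at
radius < 1.5e−6 or the iteration cap. The strategy runs coarse-to-fine over
a 3-level Gaussian pyramid (downsampling 4/2/1, anti-alias σ = factor/2
voxels), staged rigid-first: the coarse levels and the first fine-level pass
freeze scales and shears (zero step scale) so the search settles the rigid
pose before the full affine family opens up, then two full-affine passes
refine with annealed step scales (rotation-scale 0.05 → 0.02, translations
10× larger), each pass restarting the search radius. Without the staging the
12-parameter search reliably stalls in rotation/shear-compensated local
optima ~1–3° from the true pose; with it the recovered metric value matches
the value at the generator's true transform. Defaults: initial radius 0.25
(scaled units), 600 iterations per pass, seed 0. The returned transform
never scores below the identity transform.

**Evaluation metrics.** Normalized cross-correlation over all integer lags
of zero-mean volumes (unit peak for self-correlation; the peak lag reports
the displacement of the second volume relative to the first), with peak
value, peak lag and per-axis full width at half maximum (linear
interpolation of the half crossings; ties break to first occurrence in scan
order; an axis that never crosses half maximum reports NaN). Landmark
discrepancy is the per-landmark 3D Euclidean distance in µm with mean and
(population) SD across landmarks.

## Navigation

Atlas labels propagate by nearest-neighbour sampling of the label volume at
subject voxel centres mapped through the composed subject→reference→atlas
affine; labels are never interpolated, so no ids are invented. ROI signals
are spatial means over label masks, ordered by the ontology table; ROIs
below a voxel-count floor are dropped and reported.

Imaging planes are defined from two markers: u is the normalized horizontal
component of (m2−m1), v is +z (depth), the plane point is the midpoint;
markers closer than 0.1 mm horizontally under-determine the plane and are
rejected. The stage model has 4 degrees of freedom (x, y, z, yaw about the
vertical), which reaches every vertical plane — coronal, sagittal and
oblique targeting slices. The inverse solver refuses non-vertical planes
explicitly rather than approximating them, because the physical platform's
kinematic chain beyond these axes is not modelled; the model is pluggable.
Oblique slices sample trilinearly on the plane's (u, v) grid, with labels
sliced nearest-neighbour.

## Ultrasound localization microscopy

Bubbles are localized as local maxima above threshold, refined by
intensity-weighted centroid in a (2r+1)² window (a deterministic,
closed-form localizer; merge radius = PSF radius, brighter peak wins).
Frame-to-frame linking solves a gated minimum-cost assignment (Hungarian
solver on an augmented matrix with birth/death at the gating cost); the gate
defaults to the maximal expected speed over the frame rate, missed
detections may be bridged over a configurable frame gap, and tracks shorter
than 4 points are discarded. Tracks are smoothed by sliding average
(shrinking windows at the edges — collinearity is preserved, endpoints slide
along the track), linearly interpolated to 10× temporal density and
projected on a 5 µm grid: density = interpolated points per pixel, velocity
= density-weighted mean speed from finite differences × frame rate.

Misalignment between two repositioned acquisitions is measured by a
Thirion-style demons displacement field between their density maps: both
maps are Gaussian pre-blurred (σ = 2 px — near-binary super-resolution maps
otherwise carry no usable gradients), and the demons update runs
coarse-to-fine over an internal 3-level pyramid because tens-of-µm offsets
(several pixels at 5 µm) exceed the single-scale capture range for thin
vessels. The field `d` satisfies B(x+d(x)) ≈ A(x), so `d` directly reads as
the displacement of B relative to A; it is averaged over the intersection of
the dilated nonzero-density masks and reported per direction in µm. A
registration whose residual barely improves raises a convergence warning
instead of returning silently.

## Functional analysis

The design matrix holds an intercept and the stimulus boxcar sampled at the
Doppler frame rate (the standard protocol: 30 s baseline + 3×(30 s ON/30 s
OFF) at 2.5 Hz → 525 frames); convolution with a gamma hemodynamic kernel is
available behind a flag but off by default — the boxcar regressor is the
baseline model. Per voxel, ordinary least squares gives t = β̂₁/SE(β̂₁),
mapped to a z-score through the exact t→normal distributional
correspondence (not relabelled; the mapping visibly compresses the far tail)
and capped at ±38 where Φ underflows. Zero-variance voxels report z = 0.
Significance uses a two-sided test against the Bonferroni-corrected
per-voxel level α / n_voxels (0.05 over 5000 voxels → 10⁻⁵).

Connectivity: signals are zero-phase (forward–backward) 4th-order
Butterworth low-passed at 0.1 Hz — zero-phase so correlations are not
phase-biased; the filter order is the conventional default, only the cutoff
is prescribed. Pearson matrices are symmetrized with unit diagonal and a
constant ROI is an error naming the ROI; seed maps correlate the seed-mean
signal with every voxel.

## Synthetic phantoms and what they do (not) show

The generators are pure functions of (parameters, seed) and return the
latent truth downstream tests measure against.

* **Vessel trees**: binary branching with geometrically decaying radius
  (child ≤ parent) and length; the first trunk runs the box diagonal so the
  tree spans well over half of each axis, and additional roots start from
  other corners, emulating the several major vessel systems that make the
  vascular fingerprint rotationally well-determined. Power Doppler intensity
  ∝ radius² (blood-volume proxy), rendered at voxel centres
  (floor(extent/spacing)+1 samples per axis), convolved with a Gaussian PSF
  of 0.6 voxels — the device resolves ≈1 voxel per axis (100×100×400 µm),
  and unfiltered voxel-thin vessels alias under resampling in a way real
  band-limited Doppler does not. Additive Gaussian noise with
  sd = mean vessel intensity / SNR (default SNR 10), clipped at zero.
  Registration phantom pairs use two independently noisy renderings of the
  same tree on the 64×48×32 grid at (0.1, 0.1, 0.2) mm, one carried through
  a seeded rigid+scale perturbation (|t| ≤ 1 mm per axis, rotation ≤ 10°,
  scales 0.95–1.05); their cross-correlation peak at perfect alignment is
  ≈0.8–0.95, matching the reproducibility of repeated same-animal
  acquisitions.
* **Frame stacks**: tissue = exact sum of `tissue_rank` outer products of
  smooth spatial modes with slow (≤ few Hz) oscillations, so the clutter
  rank is exact by construction; blood = temporally white signal confined to
  a mask; white noise everywhere. Real tissue clutter is not exactly
  low-rank — the phantom isolates the filter's algebra, not its in vivo
  selectivity.
* **Bubble movies**: each bubble traverses one vessel centerline (projected
  to the x–z imaging plane) at a constant seeded speed (5–20 mm/s), rendered
  as a Gaussian PSF; bubbles occupy distinct vessels when possible, since
  two bubbles sharing a centerline for a whole movie are a single
  unresolvable spot. Vessels are drawn only from the usable field of view
  (a PSF window clipped by the image border biases the centroid — real
  processing crops edge detections) and, when a slab thickness is given,
  from an elevation slab around the domain centre, as a finite-thickness 2D
  acquisition sees them; bubble tracks truncate at the field-of-view edge.
  Ground-truth tracks are exact. No blinking, concentration dynamics, or
  transcranial aberration is modelled, so recovery rates here bound the
  algorithmic (not physical) error. Recovery scoring is resolution-aware:
  truth points with another emitter within ~2.5 PSF sigmas are excluded as
  unresolvable — two sub-PSF sources render as one spot that no localizer
  separates.
* **Functional series**: voxel signal = baseline·(1 + effect·regressor) +
  noise; with a correlation matrix given, noise is drawn at ROI level from
  the (PSD-checked) structure so ROI-mean correlations equal the target
  exactly in expectation. Hemodynamic delay and spatial noise correlations
  are not modelled.

Passing tests on these phantoms demonstrates the correctness of the
algorithms under their stated models; they do not certify in vivo
performance, where vascular variability between animals, skull aberration
and physiological noise dominate.

## Problem sizes used in the self-checks

The acceptance script registers 20 seeded phantom pairs on the 64×48×32
grid; ULM checks use 12-bubble, 100-frame movies; null GLM calibration uses
500 simulated runs of 2000 voxels under the 525-frame protocol; connectivity
uses 4 ROIs at 1500 samples. These sizes give stable statistics at desk
scale while each stage remains the same code path a full-scale session uses.

## Known limitations

* Volume registration is affine only; non-rigid residuals (growth,
  craniotomy, oedema) are out of scope.
* The Parzen window choice favours oracle consistency on quantized data;
  on continuous-valued volumes its MI differs from a hard-binned count by
  the (small) smoothing bias of the one-bin kernel.
* The stage model covers vertical planes only; non-vertical planes raise.
* NIfTI is the only supported volume container (no NRRD).
* The demons field is 2D and measures translation-dominant misalignment;
  rotational residuals beyond its capture range trigger a warning, not a
  recovery.
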