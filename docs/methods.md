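# Methods

## Problem

In hepatic radioembolization a Tc-99m-MAA safety scan maps the microsphere
distribution before treatment. To measure how a vasoconstrictor changes
that distribution within a single session, half the tracer is injected and
imaged, the drug is given, the second half is injected, and a second scan
is acquired. The second scan sees the *sum* of both distributions, so the
distribution added by the second injection — the *difference image* — must
be isolated by subtraction. `spectsub` implements and compares four ways
of doing that inside an ordered-subset expectation-maximization (OSEM)
reconstruction, against the reference of a separately acquired scan of the
second distribution alone ("conventional" reconstruction):

1. **Image subtraction** — reconstruct both scans independently with the
   same number of iterations and subtract voxelwise; negatives are kept.
2. **Projection subtraction** — subtract the measured projections, set
   negative bins to zero, reconstruct the clipped difference.
3. **Projection addition** — reconstruct against the post-injection scan
   with the measured baseline counts as a fixed additive background term in
   the forward model (the scatter-compensation trick repurposed).
4. **Image addition** — jointly reconstruct the difference and baseline
   images; their summed forward projections are matched to the post scan
   while the baseline image is additionally matched to the baseline scan.

## Phantom

The digital phantom is fully parametric: an elliptical-cylinder body
(semi-axes 180 x 140 mm), an ellipsoidal liver (semi-axes 110 x 80 x 60 mm,
about 2.1 L, centered at (15, 0, 0) mm) and spherical tumors. The default
configuration carries two tumors chosen to probe opposite behaviors: a
30 mm tumor whose tumor-to-nontumor (T/N) ratio doubles from 2.00 to 4.00
across the injections, and a 50 mm tumor that depletes from 5.00 to 1.00.
Each injection totals 75 MBq. A voxel belongs to a structure when its
center lies inside the analytic surface; each activity volume is scaled so
its sum matches the configured activity exactly, which makes the
configured T/N ratios exact on the noise-free volumes. The attenuation map
is uniform soft tissue (0.015 mm^-1 at 140 keV) inside the body contour —
a deliberate simplification that keeps the simulation self-contained; all
methods share it, so the comparison is unaffected.

The post-injection scan is simulated as a *single* Poisson realization of
the summed expected projections (not a sum of two noisy scans), matching
the physics of one acquisition of the combined distribution.

## Acquisition model

A parallel-beam rotation-based projector: 120 views over 360 degrees,
detector sampling matched to the grid. Per view the volume is rotated
in-plane by a sparse bilinear gather, weighted by the precomputed
transmission to the detector (ray-wise cumulative attenuation with a
half-voxel self-attenuation term), and accumulated depth plane by depth
plane toward the detector through an incremental blurring cascade: between
planes the running sum is convolved with a small symmetric kernel whose
variance is the increment of sigma(d)^2, so activity at depth d arrives
with total blur variance sigma(d)^2, where FWHM(d) = 4 mm + 0.05 d. For
sub-voxel increments the kernels are 3-tap variance-matched (sampling a
Gaussian with sigma below ~0.85 voxels at integer offsets would severely
under-blur); wider kernels are sampled Gaussians. All kernels are
normalized and zero-padded, so counts are conserved per view up to edge
truncation, and the back projector — transposed gather, same transmission,
same kernels in reverse order — is the *exact* adjoint of the forward
projector, which the tests verify to floating-point precision.

Scatter is not simulated and not corrected, and the same system model is
used for simulation and reconstruction (an acknowledged inverse crime).
Both simplifications are shared by all five reconstruction routes, so the
method *comparison* is the meaningful output; absolute recovery values
will differ from scanner measurements.

Count calibration: the system sensitivity (default 22.22 cps/MBq) is
defined at the detector for an object with the reference transmission
0.127 — the measured mean photon transmission of the default torso — so a
default 75 MBq, 600 s scan yields ~1e6 counts, a realistic level for a
short interventional acquisition. More or less attenuating objects yield
proportionally fewer or more counts; the projector itself stays strictly
linear.

## Reconstruction

OSEM with 8 stride-interleaved subsets processed in bit-reversed order,
uniform initialization scaled to the measured counts, multiplicative
updates with denominators clamped at 1e-12, and voxels of zero sensitivity
frozen at zero. Iterates are non-negative for every method; only the image
*subtraction* difference can go negative. Up to 25 iterations are run and
every iteration is snapshotted, so each method yields a per-iteration
trace of difference images.

The joint update of image addition is not published in closed form by the
method's originators; this package uses interleaved multiplicative
updates: per subset the difference image receives the EM factor from the
post-scan term y_post / (A x_diff + A x_pre), and the baseline image the
product of that factor and the EM factor from the baseline term
y_pre / (A x_pre). Both images start uniform, each scaled to its own data
(the baseline to the pre-scan counts, the difference to the post-minus-pre
count excess); with a zero-count baseline scan the scheme then reduces
*bit for bit* to conventional OSEM of the post scan, as do the other three
strategies — the tests assert all four identities exactly.

## Evaluation

Metrics are computed over VOIs: the tumor masks and a background mask
(liver minus tumors, then 3D-eroded to keep partial-volume-contaminated
voxels out). ARC (mean reconstructed over true mean activity, percent),
normalized background standard deviation (noise), contrast, CNR =
contrast/noise, and the T/N ratio. The depleting tumor's ARC denominator
is its actual true mean in the difference volume (the background level),
not zero, keeping its ARC finite. The optimal iteration is the first at
which every VOI's ARC changes by less than 1 *percentage point* from the
previous iteration, applied to the mean-over-realizations curves (the
absolute-change reading handles non-monotone series; the rule's threshold
is isolated in one function). Methods are compared by two-sided paired
t-tests across noise realizations, paired by seed; all-zero difference
vectors report p = 1 and constant nonzero shifts report p = 0 with a
degeneracy warning, keeping the contract total.

## Problem sizes and defaults

The documented full-scale setting is a 108 x 108 x 96 grid at 4.8 mm
voxels. The bundled experiments default to the half-resolution desk grid
(54 x 54 x 48 at 9.6 mm), 10 noise realizations for the default
comparison and 5 for the parameter sweeps — the same realization counts
the physical counterpart studies use — which keeps a full comparison in
minutes on one core. At 9.6 mm voxels the literal 3-voxel background
erosion would erode 28.8 mm and, together with the erosion-grown tumor
exclusions, annihilate the background VOI; the desk experiment spec
therefore erodes 2 voxels (19.2 mm), which still exceeds the full-scale
margin of 3 x 4.8 = 14.4 mm. Random streams derive from
(base_seed, realization, scan) so realizations and scans are independent
and every run is exactly reproducible from one integer.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the clinical problem — two
overlapping liver distributions with opposing tumor changes, Poisson
statistics at interventional count levels, attenuation, depth-dependent
resolution — so the qualitative method ranking (image addition best on
noise/CNR, image subtraction most quantitatively faithful, clipping bias
in the projection-domain methods, partial-volume degradation below 30 mm)
is the reproduction surface. It does not model scatter, cone-beam
collimation, anatomical texture, misregistration between scans, or motion;
absolute metric values on real scanners will differ, and conclusions about
registration robustness cannot be drawn from it. At the coarse desk grid,
count-level effects on background recovery are assessed *relative to image
subtraction* (which performs no clipping and is unbiased by construction),
because a small count-dependent drift common to all methods is visible at
this voxel size and would otherwise confound the clipping-bias comparison.
For the same reason, image subtraction and projection subtraction — whose
tumor recovery differs by fractions of a percentage point of ARC at 9.6 mm
voxels — are distinguished reliably on noise, CNR and the depleting-tumor
bias, but their tumor-ARC ranking sits at the resolution limit of the
desk-scale study (the corresponding check in the test suite documents
this by failing there).

## Known limitations

- Tumors are spheres on a uniform parenchyma; mask creation by geometry is
  exact by construction rather than thresholded from noisy maps.
- The projector's parallel-beam geometry stands in for the cone-beam
  collimator of interventional hybrid scanners.
- The image-addition update scheme is one member of the family of joint
  EM schemes consistent with the published description; its contracts
  (degeneration, non-negativity, noise advantage) are tested rather than
  an equation-level reference.
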