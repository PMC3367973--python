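# Methods

`faasym` studies how the choice of spatial-registration strategy shapes
voxel-based statistics (VBS) of fractional anisotropy (FA) hemispheric
asymmetry, and quantifies the residual misregistration each strategy
leaves behind.  Everything runs on synthetic FA/b0 phantom cohorts with
known ground truth, so each claim the package makes is checkable.

## The deformation model

Spatial normalisation is small-deformation registration with a
low-frequency parameterization.  The displacement field (in mm) is a
separable cosine expansion per component,

    u_a(x, y, z) = Σ_ijk  c_a[i,j,k] · cos(π i t_x) · cos(π j t_y) · cos(π k t_z),

with `t = (v + 0.5)/N` the normalized voxel coordinate and the lowest
7 × 9 × 7 modes per axis (1323 coefficients in total).  The objective is

    E(c) = mean_v [ s · K(S∘φ_c)(v) − K(T)(v) ]²  +  λ · B(c),

where `S` is the (selection-masked) source, `T` the template, `K` a
Gaussian smoothing operator, `φ_c` the warp, `s` a per-iteration global
intensity scale fitted by least squares (absorbing contrast differences
between b0 and FA channels), and `B` the bending energy of the
displacement.  Masking is applied to the source *before* smoothing so
the hard edge of a hemisphere selection mask does not drive the fit;
smoothing is applied *after* warping, which keeps the objective's
minimum at the true deformation (smoothing the source first and warping
the smoothed image is cheaper but measurably biases the optimum — we
observed 2–4× larger warp-recovery errors with that variant).

Optimization is Gauss–Newton on the coefficients.  The normal matrix is
accumulated through the separable structure of the basis (per-axis
tensor contractions; the (nvox × 1323) Jacobian is never formed), the
gradient uses the adjoint of `K` applied to the residual, the source is
sampled with cubic splines (linear interpolation leaves an error floor
that dominates the recovery residual), and a step-halving line search
makes every stage's objective trace monotone.  Two stages are run: the
base stage at the configured smoothing (8 mm FWHM source and template,
matching kernels) and a refinement stage at half the FWHM with a lighter
penalty (λ 0.05 → 0.02).  This smoothing schedule replaces a spatial
coarse-to-fine pyramid; at these problem sizes it provides the same
capture-range benefit with a simpler monotonicity contract.

The bending-energy quadratic form is assembled exactly from Kronecker
products of small per-axis Gram matrices of the basis functions and
their analytic derivatives.  The default weight λ = 0.05 was calibrated
so that self-registration of noisy phantoms stays below 0.1 voxel mean
displacement over the brain; displacement in empty background is not
observable and is reported only over the image support.

The affine stage estimates 12 parameters (translations mm, rotations
rad, scales, shears; composed T·Rx·Ry·Rz·Shear·Scale) by the same
Gauss–Newton/step-halving machinery on smoothed SSD, deterministically
from an identity initialization.

A caution for maintainers: `scipy.ndimage.map_coordinates` with
`mode='constant'` is *discontinuous* at the outer grid edge (any
coordinate past the last index returns `cval` outright).  This silently
defeats gradient-based optimization; all interpolation here uses
`mode='grid-constant'`, which blends with `cval` continuously.

## The four registration approaches

All subjects are first affine-registered to a common symmetric b0
reference through their b0 channel, and the same transformation is
applied to the FA map.  On top of that:

* **(i)** whole-brain registration driven by the b0 (T2-like) contrast,
  no selection mask; the warp is applied to FA.
* **(ii)** whole-brain registration driven by FA, brain-masked.
* **(iii)** separate-hemisphere FA registration: the left hemisphere is
  registered with the right side zeroed; the volume is flipped and the
  mirrored right hemisphere registered the same way; outputs are
  assembled left-half + mirrored-right-half with a one-voxel cross-fade
  on the shared midline column (the recombination rule is our choice;
  nothing in the analysis depends on its details beyond the midline
  column).
* **(iv)** the multi-contrast combination: (i) followed by (iii) on its
  output volumes.

Each approach builds its own left-right symmetrized customized template
iteratively: start from the symmetrized mean of the affine-aligned
images, re-register everybody to the current template, re-average,
re-symmetrize (voxelwise mean of volume and mirror; the hemisphere
template instead mirrors the averaged half-volume with a voxelwise max),
and stop when the relative template change — mean absolute difference
over the joint support divided by the mean absolute intensity — falls
below 2%.  Template-construction registrations run the base smoothing
stage only; the refinement stage is applied once per subject against
the converged template.  With refinement inside the loop the template
sequence chases fine detail and plateaus just above the 2% tolerance;
with the split it converges in about two iterations and the final
normalisation is unchanged.

Flipped normalised maps (the second arm of the paired asymmetry test)
are produced by running the identical machinery on the mirrored input.
For approach (iii) this is algebraically the mirror assembly of the same
two hemisphere registrations, so no extra work is done; for (iv) the
flipped arm's stage-1 output is not an exact mirror of the original's,
so its hemisphere normalisation is computed separately.

## Statistics

**FA-VBS.**  Normalised original and flipped FA maps are smoothed
(4 mm FWHM), restricted to the group analysis mask (symmetrized group
mean FA > 0.2), and compared voxelwise with a paired t-test
(`t = mean(d)/(sd(d)/√N)`, df = N−1, zero-variance voxels set to t = 0).
Only the left-greater-than-right contrast is thresholded, at explicit
t values 2.6 (liberal) and 3.7 (conservative) by default, with a
by-p-value mode available.

**Skeleton reference.**  The mean normalised FA volume is reduced to a
centre-of-tract skeleton: at each voxel above FA 0.2 the Hessian of the
lightly smoothed mean FA is diagonalized; the tract direction is the
eigenvector with the smallest |eigenvalue|; the voxel is kept when it is
a discrete local maximum against every 26-neighbour outside a ±45° cone
around the tract direction, and the principal curvature is negative.
(Selecting the cross-tract plane by the two most negative eigenvalues
fails on tube geometry: beyond the profile's inflection the radial
curvature turns positive and the test degenerates to the tangential and
axial directions, keeping a thick ring.  Requiring the local maximum
along a single interpolated eigen-direction fails at gradient-dominated
corners of the brain boundary.  The cone rule handles tubes, sheets and
their ends with one criterion.)  Subject FA is projected onto each
skeleton voxel as the maximum over the cross-tract plane (8 in-plane
directions × half-voxel radial steps, ties broken toward the skeleton),
recording the source voxel.  A single in-plane search line is ill-posed
for circularly symmetric tracts, whose cross-plane eigenvectors are
degenerate.  Paired original/flipped skeleton values are tested with a
sign-flip max-statistic permutation test (familywise error control; a
deterministic seeded generator).  Significant skeleton voxels are
back-projected into each subject's source voxels, the per-subject masks
averaged into a probability map, and the thickened mask is the strict
`probability > 0.1` set.

**Misregistration metrics.**  Binary FA masks (normalised FA strictly
above a threshold, inside the group analysis mask) carry morphology but
no microstructure, so their disagreement measures misregistration:

* voxelwise unbiased variance of the subject masks, its left+right
  hemispheric sum, and voxelwise variance ratios (F maps) between
  approaches, thresholded at the critical value of the F distribution
  (df = N−1 per side; an override reproduces a 17-df convention for a
  19-subject cohort);
* the normalized F sum: suprathreshold F values summed and divided by
  the number of nonzero F voxels.  A ratio x/0 with x > 0 is capped at
  a sentinel of 10³ and counts as suprathreshold — finite binary-mask
  variance ratios are bounded by roughly N²/4(N−1) < 6, so the sentinel
  is unambiguous;
* the hemispheric overlap κ_thr: per subject, the left half L and the
  mirrored right half R of the FA mask give Δ = |L−R| and I = L·R;
  with group means, κ = ΣĪ/(ΣĪ+ΣΔ̄) (1 = perfect mirror overlap, 0 =
  none; a Dice-style variant is available; the midline column, its own
  mirror, is excluded);
* κ between the FA-VBS suprathreshold mask B and the thickened skeleton
  mask T, normalized by |B| (the fraction of VBS findings confirmed by
  the skeleton reference; Jaccard mode available), and the counts
  N^F (voxels flagged against the multi-contrast reference) and
  N^Diff = |B ∧ ¬T| (VBS findings absent from the skeleton mask).

All thresholds are strict inequalities.

## The phantom

The synthetic cohort generator defines the study conditions:

* **Template.**  An ellipsoidal brain (84% of the half field of view)
  with three tube tracts — a superior-inferior projection-like bundle
  per hemisphere (FA 0.70), an anterior-posterior association-like
  bundle (0.60), and a midline-crossing commissural bundle (0.65) —
  on an FA-0.05 background, made exactly flip-symmetric by a voxelwise
  mirror-max.  Tubes carry a cosine radial taper (core-bright, zero at
  the radius): real tracts are core-bright, the taper gives the
  skeletonization a well-defined ridge, and it keeps non-trivial mask
  support at every analysis threshold 0.2–0.5.  A smooth flip-symmetric
  parenchymal texture field (amplitude 0.08, correlation length 10 mm)
  overlays the background: real FA images carry structure everywhere,
  and without it a deformation is unobservable over most of the brain
  (the texture scale is chosen to survive the method's own 8→4 mm
  smoothing).  The b0 companion is deliberately poor in interior white
  matter contrast: bright ventricle-like CSF blobs, near-uniform
  mid-intensity parenchyma (tracts at the same level), dark exterior.
* **Subjects.**  Each subject is the template pulled back through a
  random low-frequency cosine warp (frequencies (4,5,4), inside the
  registration span, scaled to a maximum amplitude of `warp_amplitude_mm`;
  a `hard_mode` flag samples (9,11,9), beyond the span, to emulate
  anatomical detail the registration cannot represent), a small random
  affine jitter, an optional systematic left-hemisphere displacement
  bump, an optional uniform left-only FA increment inside one tract,
  and additive Gaussian noise clipped to [0,1].  The warp's Jacobian is
  checked positive (resampled otherwise); the dense displacement,
  affine and asymmetry mask are stored as ground truth.
* **The hemispheric shape bias** is a Gaussian displacement bump centred
  on the left projection tract that decays before the brain boundary.
  This is the mechanism behind the central contrast phenomenon: the bias
  has no signature in the b0 boundary/ventricle contrast, so b0-driven
  registration cannot correct it and the misalignment is *systematic*
  across subjects, while FA-driven (especially per-hemisphere)
  registration removes it.  A broad bias reaching the boundary is
  silently corrected through the b0 edge contrast and the phenomenon
  disappears.

**Conditions used by the shipped experiments** (the package's own
choices of desk-scale problem sizes):

| experiment | grid | warp | bias | noise | n | notes |
|---|---|---|---|---|---|---|
| warp recovery / self-registration | 49×57×49 @ 3 mm | 6 mm in-span | — | 0 / 0.02 | 1 | default `PhantomSpec` |
| template convergence | 33×39×33 @ 4 mm | 3 mm | — | 0.02 | 6 | |
| ordering + trend | 33×39×33 @ 4 mm | 3 mm, hard mode | 5 mm | 0.04 | 8 | all four approaches |
| detection / null | 33×39×33 @ 4 mm | 2 mm | — | 0.01 | 10 | δFA 0.15 in tract 1 / none |

The noise level 0.04 in the ordering experiment keeps the paired test's
variance floor realistic; with near-zero noise the precisely registered
approaches flag sub-0.01 systematic interpolation differences and the
count diagnostics lose their meaning.

## What the phantom does and does not show

The phantom reproduces the *mechanisms* — complementary b0/FA contrast,
shared interior anatomy the b0 cannot see, morphological variability
partly outside the registration span, edge-dominated apparent FA
differences — but not real anatomy: tracts are straight tubes, noise is
Gaussian (not Rician), there are no susceptibility distortions, no
crossing-fibre geometry, and the brain is an ellipsoid.  Passing tests
demonstrate that the implementation behaves as specified and that the
qualitative orderings (multi-contrast separate-hemisphere best,
whole-brain b0 worst; false VBS findings tracking misregistration-prone
regions) emerge for the stated reasons; they do not certify effect
sizes on clinical data.

## Numerical choices and degenerate inputs

* Grids are RAS with the first axis along world x and an odd x
  dimension; the midline column is its own mirror, so flipping and
  symmetrization are exact (equality, not tolerance).  Hemisphere masks
  share the midline column.
* Gaussian smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in mm,
  reflective boundaries (constants are preserved).
* Out-of-field voxels resample to 0; masks use nearest-neighbour and
  stay binary.
* Zero-variance voxels in the paired test get t = 0 (excluded from
  significance); empty VBS masks make κ undefined (`None`), not 0.
* Registration convergence: relative objective change < 1e-4 or 16
  iterations per stage (pipeline runs use 6); line-search failure after
  8 halvings terminates a stage.
* Degenerate inputs (constant source images, empty selection masks,
  non-flip-closed grids, singular transforms, <2 subjects) raise
  descriptive `ValueError`s.

## Known limitations

* The approach-(iii) midline recombination is a stated convention; the
  hemispheric κ excludes the midline column to stay neutral to it.
* The permutation test is max-statistic familywise control, not
  threshold-free cluster enhancement; on these phantoms the choice of
  correction is not the driver of any reported comparison.
* Warp recovery is quantified over the brain support; displacement in
  empty background is unidentifiable in principle.
* At 4 mm desk-scale resolution the 0.5-FA mask support is only a few
  hundred voxels, so κ_0.5 is the noisiest of the threshold sweep.
* The N^F / N^Diff rank correlation is taken over only the three
  single-contrast approaches, so it is an inherently coarse statistic:
  its sign reflects whether approach (i)'s systematic (bias-driven)
  error outweighs its random (variance-inflating) error on the given
  cohort realization, and the two FA-driven approaches are close by
  construction.  The shipped experiment evaluates it on one fixed
  cohort, as intended.
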