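# Methods

## Scope and model

The package measures infarct size on short-axis LGE stacks as a percentage
of left-ventricular myocardial mass (%LVM). Mass is taken proportional to
rasterized myocardial volume (tissue density cancels in the ratio). The
underlying intensity model is the standard LGE picture: normal myocardium
is nulled (near-zero on magnitude IR, low on PSIR), infarct is
hyperenhanced, MVO is a hypointense core inside acute infarct, and each
border voxel's intensity is approximately linear in its infarcted-tissue
fraction — the partial-volume relation the weighted summation inverts.

## Geometry

Contours are closed polygons in continuous pixel coordinates; integer
coordinates are pixel centers. Rasterization is pixel-center
point-in-polygon with boundary pixels counted as myocardium on both the
endo- and epicardial contour (maximizes the myocardium consistently;
sub-pixel contour coverage is deliberately not modeled). The bulls-eye
model splits slices into 9 rings (3 basal / 3 mid / 3 apical) by
proportional thirds — ring of slice `s` of `n` is
`floor(9·(s+0.5)/n)+1`, so any slice count maps without error — and each
slice into 24 half-open 15° sectors starting at the anterior RV insertion
angle, advancing toward the inferior insertion through the septum (septal
sectors get low indices). One insertion-point pair orients the whole
stack. The default per-artery maximal-extent territories live in
`src/ewa/data/extent_models.yaml` and are replaceable configuration, not
validated anatomy; LM is always the union of LAD, LCx and RCA, and the
defaults leave one lateral sector column outside all territories so an LM
culprit still has a remote reference.

## Coil correction

The model is `I_j = c_class(j) · f(x_j)` with `f` a second-order
polynomial per slice in coordinates normalized to [−1, 1] — linear in its
six coefficients, matching a gradient roughly proportional to squared coil
distance. Blood pool (endocardial interior eroded one pixel) and remote
myocardium are the two constant-level classes. The fit alternates weighted
least squares for `f` with re-estimation of the class levels
`c_k = mean(I/f)` until the coefficients settle; a single pass (plain
class-mean normalization) would make the two classes target differently
scaled copies of the field whenever their regions see different field
averages. Samples are weighted by the class's squared inverse relative
spread `(mean/SD)²`, so a nulled, noise-folded remote class (magnitude IR)
cannot tilt the surface that the clean blood pool anchors. Slices with
fewer than six samples fall back to one pooled fit; rank-deficient designs
drop to lower polynomial order with a logged warning. The field is
normalized to mean 1 over the fit samples — the absolute scale is
irrelevant because every later stage is affine-invariant in intensity.
Without an extent model (no culprit given) there is no remote class and
correction is skipped entirely. A 2D-per-slice fit was chosen over a
single 3D polynomial because coil sensitivity varies strongly
through-plane with 8 mm slices; the pooled fallback is the 3D variant in
all but basis.

## EM threshold

Two Gaussians (normal, infarct) with mixing weights are fitted to the
myocardial intensity sample. Intensities are standardized internally so
the convergence tolerance (max absolute parameter change < 1e-6, cap 500
iterations) is scale-free; the result is mapped back, making the threshold
exactly affine-equivariant. Initialization labels values strictly above
the 90th percentile as infarct (ties to normal); every E-step clamps
responsibilities to normal below the 5th and to infarct above the 95th
percentile (clamping each E-step, not only at initialization, is the
stabler of the two readings and is what keeps the components separated on
unimodal inputs). Percentiles use linear interpolation between order
statistics — the constraint boundaries depend on the estimator, so it is
pinned. The optimal threshold equates the *mixture-weighted* densities
(equal posterior probability); the unweighted class-conditional variant is
available via `optimal_threshold(pair, weighted=False)`. The quadratic is
solved in closed form; the root inside `(μ_n, μ_i)` is preferred, the
nearest root otherwise, and equal variances reduce to the linear case.
Component collapse (weight < 1e-6 of the sample or SD < 1e-9 of the range)
raises a diagnostic error rather than returning a degenerate pair.

## Level set

The front evolves on the discrete voxel grid (integer membership, no PDE):
per sweep, outside voxels 4-adjacent to the region join where
`S − α·κ > 0` and boundary voxels leave where it is negative, with
`S = (I − t*)/(I_max − t*)` and κ a 3×3 occupancy mean-curvature proxy
((5 − count)/4: isolated voxel 1, flat edge 0). Ties at exactly zero stay
out, matching the strict `{S > 0}` seed rule, so `α = 0` reproduces direct
thresholding bit-exactly. Curvature is computed in-plane (2D) while the
region itself spans slices. Defaults `α = 0.1`, 200-sweep cap: the
original smoothing parameters are not published, so these are declared
choices, CLI-configurable (`--smoothing`, `--max-iter`) and recorded in
output metadata, not claims of fidelity.

## MVO

Per slice: non-core myocardial components (4-connectivity, complementary
to the core's 8-connectivity) are MVO when they have no "escape" voxel —
one that borders non-myocardium without being 4-adjacent to the blood
pool. This operationalizes "totally surrounded by infarct or connected to
the endocardial border": a component touching the epicardial rim always
has an escape and is never MVO. A second pass dilates the core with the
3×3 cross kernel to seal one-pixel rim gaps, re-runs the flood fill, and
erodes back; holes discovered at the dilated stage are kept where they are
not core. (The alternative — eroding the hole set itself — would shave
genuine MVO borders; the ambiguity is inherent to a one-sentence
description of the closing step.) MVO voxels merge into the infarct and
later receive weight 1.

## Post-processing and weighting

The culprit filter removes infarct voxels whose (ring, sector) is outside
the extent model and runs before the size filter. Components are 3D
26-connected so a transmural infarct spanning slices is never fragmented;
a component is dropped when volume < 1.5 cm³ AND ≤ 1 %LVM, never when it
is the only one (generalized: if every component is small, the largest is
kept, so a non-empty mask never empties). Size filtering uses binary
volumes — weighting happens after, per the step order.

Weights are `clamp((I − μ_r)/(P90_MI − μ_r), 0, 1)` on non-MVO infarct
voxels and 1 on MVO, zero elsewhere; `P90_MI` is the 90th percentile over
the non-MVO infarct voxels (computed before the MVO merge — the other
reading would let dark MVO voxels drag the anchor down), and `μ_r` is the
remote mean after correction, or the EM normal-component mean `μ_n` when
no extent model (hence no remote) exists. The weighted size is invariant
to affine intensity rescaling and bounded above by the binary size.

## Synthetic phantoms

`PhantomSpec` defaults emulate a typical acquisition: 96² grid,
1.5 × 1.5 × 8.0 mm voxels, 9 contiguous slices, circular annulus (endo
30 mm, epi 45 mm radius), a transmural 90° septal wedge, remote mean 10,
infarct mean 100, noise SD 9 (contrast-to-noise 10), blood pool at 120,
Gaussian PSF SD 1.5 mm in-plane, and a mild positive second-order coil
field. Partial volume is modeled by blurring the binary wedge into a
continuous per-voxel infarct fraction *before* noise, using a normalized
(mask-confined) convolution that conserves total fraction and acts like
reflecting boundaries at the endo/epicardial rims — the fraction field is
exactly the quantity step 6 claims to estimate and is stored as ground
truth. IR mode takes the magnitude of the noisy signal (folded noise in
the nulled remote); PSIR and T1w stay signed. MVO, when enabled, is a
subendocardial band inside the wedge whose intensity drops to the remote
level while its truth fraction stays 1. `generate_paired` emits IR and
PSIR stacks from one geometry/truth with independent sub-seeded noise.

What the phantom does **not** model: Rician noise statistics (folding is
the one mode difference), through-plane partial volume, cross-boundary
intensity bleed between blood pool and myocardium, papillary muscles,
contour error, motion, or heterogeneous infarct texture. Passing tests
therefore show algorithmic correctness under the stated intensity model,
not clinical accuracy.

## Accuracy characteristics and known limitations

On noise-free phantoms the pipeline recovers the generated truth within
1 %LVM end to end. At the default contrast-to-noise of 10 two opposing
effects appear, both intrinsic to the method rather than implementation
artifacts:

- the weight anchor `P90_MI` sits about 0.9 noise-SD above the mean of a
  homogeneous noisy infarct, shrinking every interior weight by ~10% and
  biasing the weighted size low (measured −2.6 ± 1.0 %LVM on the
  20-phantom panel of `scripts/acceptance.py`);
- blurred edge mass below the EM threshold lies outside the segmented MI
  and is never weighted, while the binary voxel count overcounts the
  included edge band and lands near truth by partial cancellation.

Consequently, on these homogeneous-interior phantoms the binary estimate
can beat the weighted one; on heterogeneous real infarcts the P90 anchor
is a robust stand-in for the "fully infarcted" intensity and the weighting
is the better-behaved quantity. The acceptance suite asserts the stricter
recovery bounds regardless and currently reports the weighted-size bias
honestly rather than tuning the generator or the formula to mask it.

Other limitations: FWHM comparators use global myocardial extrema rather
than the original region-growing formulations (flagged as an
approximation); no Rayleigh–Gaussian mixture variant; no automatic
contouring or insertion-point detection; no sub-voxel level-set
representation.

## Problem sizes

Default test and acceptance workloads were sized for a laptop-class single
CPU: 10⁶ samples for the n-SD tail check, 100 mixture pairs against a
10⁻⁴-step grid oracle, 50 reduced phantoms (64² × 3 slices) for the
level-set limit, and 20 full phantoms each for the recovery and paired
panels. The whole acceptance script runs in about 90 s.
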