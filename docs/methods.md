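# Methods

This note documents the models, numerical choices and limitations behind
`tacicp`, in the order the pipeline runs them.

## Data model

The only raw input is a stack of closed 2D lumen polygons, each in a plane
of constant z (the slice axis), in millimetres, carrying a vessel label
(CCA / ICA / ECA, or UNLABELED on input). Slices hold 1–3 contours and never
two contours of the same vessel. Contours are implicitly closed (the first
vertex is not repeated) and must have nonzero signed area. Vertex winding is
not normalized on input: the shoelace centroid is winding-invariant because
its numerator and denominator flip sign together.

## Features

**Centerline** (rigid step). Per vessel, the area centroids of the contours
are lifted to 3D with their slice z, interpolated with a chord-length
parameterized interpolating cubic B-spline (no smoothing — the centroids are
already a generalized mean filter over the contour vertices) and resampled
at equal arc-length steps of 1 mm (default). Vessels with fewer than four
slices fall back to linear interpolation; with fewer than two they are
skipped with a warning. The centroid is computed with exactly rounded
summation (`math.fsum`), which makes it bitwise invariant to vertex-order
reversal and cyclic rotation.

**Surface samples** (non-rigid step). Per vessel, every contour is resampled
to 32 equal-arc-length vertices, oriented counter-clockwise and started at
the vertex of maximal x relative to the contour centroid; this puts rings in
deterministic azimuthal correspondence across slices. The 32 vertex tracks
are interpolated along the vessel with cubic B-splines and evaluated at
enough intermediate rings that the total sample count approaches the target
(3500 by default), allocated to vessels proportionally to centroid-path arc
length. The azimuthal start rule is deliberately frame-anchored rather than
rotation-equivariant: extracting a surface from a rotated stack samples the
same surface with a ring-phase shift of up to half the azimuthal spacing
(≈0.3 mm at 32 vertices on a 3 mm radius). This is the sampling floor
visible in surface metrics between independently sampled copies of one
surface.

## Conditional ICP

The match stage minimizes the label-weighted distance
`w_{L_m, L_f} · ‖m − f‖` over fixed points, per moving point. Weights:
`w0 = 1` on the diagonal, `w1` for CCA↔branch pairs, `w2` for ICA↔ECA.
Defaults `w1 = 1`, `w2 = ∞`. An infinite weight with zero distance counts as
conditional distance 0; in practice an infinite weight simply removes the
label subset from the candidate pool. Implementation: one KD-tree per fixed
label, queried per moving-label group, weighted minima compared across
groups; ties go to the smallest fixed index. This reproduces the exhaustive
O(N²) scan exactly (tested against it).

The transform stage is shared across labels and pluggable:

* **rigid** — closed-form Kabsch/Horn SVD solve with determinant correction
  (no reflections). The public `estimate_rigid` rejects collinear
  correspondence sets; inside the iteration loop a transiently rank-deficient
  cross-covariance (it happens under a deliberately wrong label candidate)
  is tolerated, since any minimizing rotation keeps the MSE non-increasing
  and the next match recovers.
* **tps** — one thin-plate spline refitted each iteration from the original
  moving points to the current correspondences (see below).

The loop starts at the identity, records the mean squared matched error
after every transform stage, and stops when the MSE falls below `tol`
(1e-4 mm², an artifact choice — observed convergence is 2–4 iterations),
when its decrease is below `tol`, or at 50 iterations. For `w1 ∈ {1, ∞}`
every selected pair weight is constant across iterations, so the matched
distances cannot increase and the rigid stage (an exact minimizer that can
always fall back to the identity) yields a provably non-increasing MSE
trace. The regularized TPS stage minimizes data + λ·bending rather than the
raw data term, so the raw MSE can in principle rise marginally when a refit
trades fit for smoothness; a monotone safeguard rejects such a step (keeping
the previous, better transform) and stops. The safeguard never fires for
the rigid model.

An opt-in `pre_translate` flag aligns the two point-set centroids before the
first match. It is off by default — the intended workflow needs no manual
pre-alignment because clinical acquisitions are centered on the bifurcation
— but it matters for large pure translations: identity-start ICP on a
1 mm-resampled centerline otherwise locks into axial lattice minima about
one sample interval off. The rigid-recovery tests use this mode.

## Thin-plate spline

The 3D TPS maps `f(x) = D·[1,x]ᵀ + P·φ(x)` with `φ_j(x) = ‖x − m_j‖`,
`D` a 4×4 homogeneous affine and `P` a 4×N warp whose rows satisfy the
side conditions `P·[1|m] = 0` (the kernel part carries no affine component).
The fit solves the classical bordered smoothing system. Two numerical
choices matter:

* **Kernel orientation.** The Euclidean distance matrix is conditionally
  *negative* definite, so the smoothing system is a minimizer only in the
  −r orientation; solved with +r it is a saddle and the coefficients blow
  up. The solver uses −r internally and flips the sign of the stored `P`,
  so the public transform uses the +r kernel written above, exactly.
* **Normalization.** Control points are centered and scaled to unit RMS
  radius before solving (mm-scale kernel systems are ill-conditioned), the
  regularizer is rescaled by 1/s so that λ keeps its meaning against
  mm-scale residuals, and the normalization is folded back into `D` and `P`
  (the warp coefficients transfer unchanged because the kernel is
  1-homogeneous).

λ defaults to 1. At λ = 0 the fit interpolates exactly; affine target fields
give `‖P‖ ≈ 0` at every λ; the data residual is non-decreasing and the
bending energy non-increasing in λ (all tested). Control points are capped
(default 800) by deterministic farthest-point subsampling: a dense system on
3500 surface samples is needlessly expensive and the spacing-maximizing
subset preserves the deformation field.

## Auto-labeling

Slices with one contour are CCA. For two-contour slices the two contours are
put in a deterministic in-slice order (ascending centroid x, ties by y) and
the two candidate orderings, ECA-ICA and ICA-ECA, are both registered
rigidly against the labeled fixed stack. Each candidate is scored by LMSD of
its rigidly transformed surface under its *own* labels; the smaller score is
chosen (ties: ECA-ICA, with a warning). Any fixed in-slice rule works
because both candidates are tried. On branch-symmetric anatomies the two
scores coincide up to noise — that is the method's documented failure mode,
and the phantom's default branch asymmetry (ICA 2.4 mm vs ECA 1.6 mm,
25°/30° branch angles) exists so tests exercise the asymmetric regime.

## Metrics

LMSD/LMAXD are asymmetric (moving → fixed), exactly as defined; a symmetric
average is available behind a flag. Compatibility allows same-label and
CCA↔branch pairs, never ICA↔ECA. RSR counts cases with LMSD *strictly*
below the threshold (1.5 mm default). The per-position profile bins moving
points by z relative to the bifurcation slice, defined as the lowest-z slice
containing two contours.

## Synthetic phantoms

The generator emulates what the algorithm actually consumes: labeled
per-slice contours of a bifurcating vessel. CCA is a circular tube on the
z-axis (radius 3 mm, length 20 mm by default); ICA and ECA are straight
oblique circular tubes (radii 2.4 / 1.6 mm, tilts 25° / 30° toward ±x)
whose constant-z cross sections are ellipses; `branch_length_mm` (16 mm) is
the vertical branch extent so both branches span the same slices. Branch
axes are offset laterally by the smallest amount keeping the two contours
disjoint in every slice (+0.2 mm margin); a user-supplied offset that makes
them overlap is a validation error. Slice spacing defaults to 0.4 mm.
Branches are straight so the ground truth stays closed form; bending enters
only through the deformation.

A deformation applies, in order: a sinusoidal lateral bend
`Δx = A·sin(2πz/λ_w)`, a twist about z linear in z, a rigid motion, then
re-slicing of each vertex track at the original z grid (linear
interpolation; a track that loses z-monotonicity — extreme rotation plus
bend — is an error), and finally optional zero-mean Gaussian noise of given
σ added independently to the x and y coordinate of every re-sliced vertex
(never z), matching how segmentation error perturbs 2D contours. The exact
noiseless displacement map is returned for ground-truth scoring. Everything
is deterministic given the seeds.

What the phantom does **not** emulate: curved branch axes, a merged
bifurcation apex (the three tubes are independent), lumen eccentricity and
plaque, modality-dependent contour bias between the fixed and moving stacks,
and anisotropic segmentation error. Passing tests therefore demonstrate the
algorithm's correctness and its robustness mechanisms, not clinical
accuracy on real US/MR pairs.

## Problem sizes and study conditions

Defaults mirror a realistic acquisition: 0.4 mm slices, ≈3500 surface
samples and ≈90 centerline samples per image; `scripts/acceptance.py` runs
at this scale. The pytest suite uses coarser phantoms (0.8–1.0 mm slices,
900–1200 surface samples, 250–300 TPS control points) — the package's
choice of test scale; every property tested is scale-free. Deformation
magnitudes for the two-step-benefit trials are rotations of 8–20°,
translations up to 6 mm, bends of 0.8–2 mm and twists of 2–6°/cm,
representative of neck-position changes between scan types. The noise sweep
follows the σ = 0.2…2.0 mm (step 0.2), 3-repetition design, and evaluates
ΔLMSD with the transform fitted on noisy contours applied to the *clean*
moving surface, isolating registration degradation from the noise itself.

## Known limitations

* Rigid parameter recovery through re-sliced stacks with a large z-shift is
  biased by partial overlap (truncated tubes); the controlled recovery
  claims are made on full-overlap point sets.
* Tangential sliding along a tube is unobservable to surface metrics; the
  ground-truth TRE reported by `evaluate` exposes it, and it can be several
  times the LMSD.
* The TPS transform is not invertible and is evaluated one-way
  (moving → fixed).
* Auto-labeling requires 1 or 2 contours per slice (no plaque-split lumens).
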