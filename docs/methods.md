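# Methods

This note documents the models, numerical choices and limitations of
`petas3d`. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## Segmentation model

The biological tumor volume is the interior of a closed surface *S*
represented implicitly as the zero level set of a scalar field φ on the
voxel grid, negative inside. *S* minimizes a localized region-based energy
with two terms, balanced by λ:

* **Intensity term** (weight 1−λ): for each narrow-band voxel x, the SUV
  values inside the spherical neighborhood B(x, l) are compared against the
  localized interior mean u_l(x) (over B(x,l) ∩ {φ<0}) and exterior mean
  v_l(x) (over B(x,l) ∩ {φ≥0}). Localized means, rather than global ones,
  let the surface adhere to locally varying uptake; in the limit l ≥ grid
  diameter the model reduces exactly to the global piecewise-constant
  (Chan–Vese) model, which the implementation exploits as a computational
  shortcut and the tests exploit as an oracle.
* **Classification prior** (weight λ): the three-class tissue classifier
  yields characteristic maps χ_lesion, χ_border, χ_background that
  partition the grid. P̄_in(x) and P̄_out(x) are the fractions of B(x, l)
  classified lesion and background. Interior voxels pay P̄_out, exterior
  voxels pay P̄_in: conflicts between the surface and the classifier are
  penalized, and border-line tissue — windows straddling the tumor edge —
  is deliberately neutral.

The surface measure dS is realized on the narrow band by the smoothed
Dirac δ_ε(φ) = (1/2ε)(1 + cos(πφ/ε)) for |φ| < ε, with ε = 1.5 voxels; the
reported energy is normalized per band voxel so runs of different surface
area are comparable.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| λ | 0.01 | — | prior weight; small because squared SUV residuals are numerically much larger than the [0,1] prior fractions, and the prior need only act where intensity contrast vanishes |
| l | 3 | voxels | localization radius; a sphere in index space, matching the 3×3×3 window convention of the classifier |
| α | 0.35 | — | curvature regularization weight (see below) |
| dt | 0.45 | voxels | CFL-safe step; the combined speed is bounded to [−1, 1] |
| ε | 1.5 | voxels | Dirac half-width |
| conv_window / conv_flip_tol | 10 / 10⁻⁴ | iters / fraction | convergence: the narrow-band sign-flip fraction stays below tol for a full window |
| reinit_every | 10 | iters | signed-distance rebuild period; equal to conv_window by design |
| max_iter | 500 | iters | safety net only; hitting it is flagged as "not converged" |

### Descent discretization

The descent direction at x is
`g(x) = λ(P̄_out − P̄_in) + (1−λ)[(SUV − u_l)² − (SUV − v_l)²]`; negative
values pull the voxel inside. The update is

```
φ ← φ + dt · (ε·δ_ε(φ)) · [ tanh(g / s) + α·κ ] / (1 + α)
```

with κ the mean curvature of φ (central differences, clipped to [−1, 1])
and s the mean of |g| over the band. Three choices here deserve
justification:

* **Robust squashing instead of sup-normalization.** Dividing by the
  band's maximum speed freezes weak forces: with λ = 0.01 the prior moves
  the front by ~10⁻⁴ voxels per iteration wherever a strong intensity edge
  exists elsewhere in the band, so large initializations never contract
  across flat background. `tanh(g/s)` preserves sign and monotonicity of
  the gradient but compresses the dynamic range, so systematic weak forces
  act at a useful pace while the strongest voxels saturate at one step.
* **Curvature term.** The energy itself carries no smoothness penalty; the
  bare discrete flow is unstable under voxel noise (the interface turns
  fractal and sheds disconnected specks). A mean-curvature term with
  weight α is added as an extension. α = 0.35 sits in the window where the
  noise-driven flow stays clean but genuine topology changes still happen:
  at α ≤ 0.2 the noisy flow fragments; at α ≥ 0.5 a toroidal handle cannot
  pinch open. α = 0 recovers the unregularized gradient and is used by the
  energy-descent and oracle tests.
* **Sign-preserving reinitialization in the loop.** Every `reinit_every`
  iterations φ is rebuilt as the exact-Euclidean signed distance (EDT with
  a half-voxel interface correction) of its current sign pattern. This
  keeps the voxel partition — and therefore the flip-fraction convergence
  statistic — untouched. The public `reinitialize` operation instead
  solves the relaxation PDE φ_τ = S(φ₀)(1 − |∇φ|) with Godunov upwinding
  and the Russo–Smereka subcell anchor; it preserves a true distance field
  exactly and is the right tool for repairing a field whose sub-voxel zero
  set must not move, but iterating it inside the evolution loop drifts the
  interface by accumulation of its first-order error, which measurably
  degraded converged masks — hence the EDT rebuild in `segment`.

Reinitialization is deliberately synchronized with the convergence window
(`reinit_every = conv_window`): the front can stall when it outruns the
δ-band between rebuilds, and a stalled front must not be mistaken for a
converged one. Since every quiet window spans a rebuild, stability is only
declared when a fresh signed-distance field also produces no flips.

### Convergence

The stop criterion is topological stability: the fraction of narrow-band
voxels (|φ| ≤ l+2) whose sign flips must stay below 10⁻⁴ for 10
consecutive iterations. There is no tuned iteration count; `max_iter` is a
flagged safety net. The energy history is monitored, and a >1% increase
over any 10-iteration window raises a warning — with curvature enabled
(α > 0) the monitored energy may legitimately rise early while the
regularizer reshapes the init, since κ is not part of the tracked
functional.

## Tissue classifier

Linear discriminant analysis with a pooled within-class covariance over
27-element window vectors (flattening order: first grid axis fastest,
documented so serialized models are portable). The pooled 27×27 covariance
is rank-deficient when background windows are near-constant, so a ridge
γI is added, γ defaulting to 10⁻⁶·trace(Σ)/27. Class priors are used as
fitted; the ~100:1 class imbalance of realistic volumes is left intact
because the discriminant scores, not balanced error, drive the prior maps.
Training uses a seeded stratified 80/20 split with held-out metrics
attached to the model; stratified k-fold cross-validation (default k = 5)
is available for robustness checks. Whole-volume classification
edge-replicates the border so every voxel receives a label, while training
extraction is interior-only to keep labels pure.

ROC analysis is lesion-vs-rest: the score is the lesion discriminant minus
the best competing class, and the AUC is computed by the rank (Mann–
Whitney) formulation with ties counted ½, identical to the trapezoidal
integral of the ROC curve.

## Pre-segmentation

The user ROI (a box or mask roughly encircling the lesion) is reduced to
an ellipsoid initialization in three steps: (1) the maximum-uptake voxel
in the ROI (ties break to the lowest flat index, deterministically);
(2) the 26-connected component, containing that voxel, above 40 % of the
maximum — the common PET thresholding practice; (3) a second-moment
ellipsoid of the seed, semi-axes scale·√eigenvalues with scale = 2.5
(slightly above √5 ≈ 2.24, which would reproduce a solid ball exactly), 
floored at 2 voxels, grown uniformly if needed so it contains the maximum
voxel. Seeds under 4 voxels or coplanar fall back to a radius-3 sphere.
Moments are computed in voxel units so the ellipsoid lives on the index
grid like φ. For multi-component lesions the threshold seed is a single
component by construction; an initialization that should envelop several
disjoint targets must be built over the full ROI extent (the acceptance
experiments do exactly this) because a localized flow cannot jump to a
blob it never touches.

## Synthetic phantoms

The generator emulates what matters to the segmentation problem: an
anisotropic grid (default 64×64×48 at 2.73 × 2.73 × 3.27 mm), a bright
tumor over dim background (defaults 8.0 / 1.0 in SUV-like units),
isotropic Gaussian PSF blur specified as world-space FWHM (default 4 mm,
a typical post-reconstruction PET resolution), additive Gaussian noise
(default σ = 0.4, i.e. 5 % of tumor uptake; a scaled-Poisson option
exists), and five tumor geometries — sphere, ellipsoid, bilobed, torus,
two disjoint blobs — sized by one radius parameter (default 25 mm,
a ~65 mL clinical-scale volume). The gold mask is the exact center-inside
test of the implicit shape; partial volume enters only through the PSF on
the intensity image, so the reference is unambiguous.

What the phantoms do **not** emulate: spatially correlated reconstruction
noise, scatter and attenuation artifacts, heterogeneous tracer uptake
inside the lesion, physiological uptake in neighboring organs, and
respiratory motion blur beyond the isotropic PSF. Passing tests on these
phantoms therefore demonstrates correctness of the machinery and behavior
under idealized PET-like contrast, not clinical performance: per-voxel
independent noise is in fact *harsher* on the flow than smooth
reconstructed noise of equal amplitude, but real lesions are less
homogeneous than these.

## Evaluation

Confusion counts are voxelwise; the five rates follow their textbook
definitions, with the 0/0 case defined as 1.0 and flagged so degenerate
sweeps do not crash. The Hausdorff distance is computed between surface
voxel sets (mask voxels with a face-adjacent background voxel or grid
edge) — equivalent to the boundary Hausdorff of solid masks and much
faster — via KD-trees, in voxel units by default or per-axis-scaled mm.
Pearson correlation serves paired per-case score lists.

## Numerical edge cases

* Empty interior or full-grid initializations are rejected before
  evolution; a surface that collapses entirely during evolution simply
  stops flipping and converges to the empty-or-full partition it reached.
* Localized means with an empty side fall back to the global side mean
  (then to the volume mean), so u/v are always defined.
* `ball_sum` uses exact direct convolution on small problems and FFT
  convolution on large ones (crossover at 4·10⁷ voxel·taps); counts from
  the FFT path are rounded back to integers. When l covers the whole grid
  the sum is computed globally and exactly.
* All randomness (phantom noise, splits, folds) flows from integer seeds;
  identical configs are bit-reproducible, including the gzipped NIfTI
  artifacts.

## Problem sizes

The default grid (64×64×48) keeps a full pipeline run at a few seconds on
one CPU, and the complete test suite at ~2 minutes; oracle comparisons
run on ≤ 11³ grids where triple-loop reference implementations are cheap.
The clinical 256×256 in-plane matrix is supported but not the default.

## Known limitations

* The boundary found by the prior term alone sits where the ball-averaged
  lesion and background fractions cross, which for a convex lesion is
  biased inward by roughly l²·κ/2 voxels (κ the surface curvature); this
  is negligible for lesions much larger than l but visible on small
  spheres.
* The localized flow only moves where the δ-band overlaps contrast; it
  cannot discover lesions disjoint from the initialization.
* Linear DA assumes shared within-class covariance; strongly heteroscedastic
  tissue statistics would favor quadratic DA, which this package does not
  implement.
* SUV conversion is plain body-weight SUV on decay-corrected activity;
  no decay model, lean-body-mass or BSA variants.
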