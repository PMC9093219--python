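# Methods

This note documents the models, numerical choices and defaults behind
`cbctrec`, and what the shipped synthetic experiments do and do not show.

## Scan model and projector

The acquisition is discretised as y = A x with aᵢⱼ the exact length (mm) of
ray i inside voxel j. Conventions, fixed for bit-reproducibility: world
coordinates in mm with the isocenter at the origin; the source orbits in the
z = 0 plane, at angle θ it sits at (D_so cos θ, D_so sin θ, 0); the flat
panel is perpendicular to the source–isocenter line with its column axis in
the orbital plane and its row axis along z; view angles are equispaced over
the full circle (no short-scan weighting); voxels are indexed 0-based in
C-order with the grid centred on the isocenter unless offset.

A and Aᵀ are never materialised. Both directions run the same Siddon
parametric traversal (slab-clipped entry/exit parameters, incremental
plane-crossing updates), so the pair is adjoint by construction; the test
suite verifies ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ to 1e−10 relative and per-ray length sums
against the analytic entry–exit chord to 1e−9 relative. Rays that miss the
volume have zero row sum and are excluded from all algebraic updates. The
kernels are numba-compiled; a 64³ volume with 32 views of 128² rays costs
roughly 0.4 s per full projection on one CPU core.

## Phantom and simulation

The built-in phantom is a ten-ellipsoid 3-D Shepp-Logan-style head (values
in [0, 1]), scaled to 90 % of the grid's smallest half-extent. It is
piecewise constant: its gradient-magnitude image is nonzero only on
ellipsoid surfaces, which is precisely the sparsity assumption behind
TV/TpV regularisation. Simulation is the Siddon forward projection,
noiseless by default; an optional Poisson photon-counting model
(I ~ Poisson(I₀ e^{−y}), y′ = −ln(max(I,1)/I₀)) is seeded and reproducible.

Two caveats about what the phantom does *not* emulate: real anatomy has
texture, so a strongly converged gradient-sparse prior is flattered here
relative to clinical data (piecewise-constant ground truth is the TV/TpV
prior's best case); and there is no scatter, beam hardening or detector
blur. Passing orderings on this phantom demonstrate correct mechanics and
the direction of each regulariser's trade-off, not clinical image quality.

### Demo geometry

The clinical distances (source–detector 1040 mm, source–origin 570 mm) are
used as defaults. The simulated panel is not specified by any external
reference, so it is sized by the standard sampling rule: the detector pixel
footprint at the isocenter should match the voxel size. At magnification
1040/570 ≈ 1.82, 2.0 mm pixels give a 1.1 mm footprint for the 1 mm demo
voxels; 128×128 pixels cover the projected bounding sphere of the 64³ grid
with margin. An undersampling panel would add per-view aliasing streaks to
every algebraic method and would confound the regulariser comparison.

## SART

Implemented exactly as the per-view additive correction with ray-sum and
voxel-sum normalisation. The correction sign is measured-minus-estimated
(the opposite sign, as sometimes printed, diverges from the data — a known
typography trap). One iteration = one full pass over all views in ascending
angle order; λ (default 1) decays by λ_red (default 0.99) once per pass.
Iterates are clamped to x ≥ 0 after every view update, consistent with the
nonnegativity constraint of the regularised problems. On small consistent
full-rank systems with all rays in one subset the iteration converges to
the direct solution to machine precision (tested); with cycled subsets a
small limit cycle can persist, which is why the oracle test uses the
single-subset grouping.

## TpV by alternating direction minimization

The model minimises the ℓ_p quasi-norm (0 < p ≤ 1, default 0.9) of the
per-voxel gradient magnitude subject to y − Ax = e, ‖e‖₂² ≤ ε, x ≥ 0.
Splitting z = ∇x and dualising both constraints gives the cycle

1. z ← S_{β₁,p}(∇x + λ₁/β₁), applied isotropically through the per-voxel
   Euclidean magnitude of the three gradient components;
2. x ← pos(F⁻¹[F[∇ᵀ(β₁z − λ₁) − Aᵀ(λ₂ + β₂(Ax + e − y)) + β₂τx] / J]);
3. e ← Euclidean projection of y − Ax onto {‖e‖₂² ≤ ε}
   (e = r·min(1, √ε/‖r‖₂); the exact projection, not the r·ε/‖r‖₂²
   scaling that a literal reading of some printed variants suggests);
4. λ₁ ← λ₁ − ηβ₁(z − ∇x), λ₂ ← λ₂ − ηβ₂(y − Ax − e).

Numerical choices:

* **Gradients** are forward differences with periodic boundaries in voxel
  units; the divergence is the exact negative adjoint (unit tested), and
  ∇ᵀ∇ diagonalises under the 3-D DFT with eigenvalues Σ 4 sin²(πk/n).
  Periodicity is required for the FFT solve; its wrap-around coupling is
  negligible because the phantom is zero near the boundary.
* **Proximal linearisation.** The data term is linearised at x^(k) with
  weight τ: d = Aᵀ(Ax + e − y) enters the right-hand side and
  J = β₁Λ + β₂τ is the Fourier-domain denominator. τ defaults to 1.1× a
  10-step seeded power-iteration estimate of ‖AᵀA‖; smaller τ values
  (≤ 0.5×) were observed to destabilise the iteration.
* **p-shrinkage** is the single-step generalized mapping
  s_{β,p}(t) = max(t − β^{p−2}t^{p−1}, 0). It is exact soft thresholding at
  p = 1 and agrees with the exact (grid-searched) ℓ_p proximal point to
  within ~2 % of max(t, 1) at p = 0.9 (tested); no inner iterative
  refinement of the mapping is performed.
* **Defaults** β₁ = 10, β₂ = 1, η = 1.5 (stability bound (1+√5)/2) were
  fixed once on the built-in head phantom; ε = 0 for noiseless data (then
  e ≡ 0 and the multiplier accumulates the full residual). Stopping is a
  fixed iteration count; an optional relative-change tolerance is exposed
  but disabled by default so that matched-budget comparisons and
  equivalence tests run identical iteration counts.
* **Divergence guard**: the solver raises if the data residual grows 10×
  above its recent minimum *and* above its initial value (transient
  multiplier oscillations near convergence are not divergence).

At p = 1 the solver reproduces an independently written classical TV-ADM
(soft thresholding, its own operators and FFT symbol) to 1e−6 — the
non-convex machinery reduces exactly to the convex special case.

## Baselines

Both baselines alternate a SART pass with steepest descent on a smoothed
isotropic TV (δ = 1e−8), each descent step along the normalised gradient
with backtracking so the inner loop never increases TV.

* **ASD-POCS**: each inner TV step has length α·dp, where dp is the
  magnitude of the preceding SART update and α = 0.002 — descent is strong
  while the data update is large and fades as the iterate stabilises.
* **SART-TV**: inner steps of length λ_TV·3e−2·dp with λ_TV = 15 and 20
  inner steps per pass. λ_TV scales the TV descent (λ_TV → 0 recovers plain
  SART, tested); the 3e−2 scale constant is a package choice that places
  λ_TV = 15 in the strongly smoothing regime this combination is known for
  on piecewise-constant objects — it suppresses streaks aggressively at the
  price of fine structure, and correspondingly scores worst of the five in
  the demo experiment.

## TpV-GIF

The guided filter fits Q = aI + b per (2R+1)² window of the guide I
(a = cov_IP/(var_I + ε), b = mean_P − a·mean_I, coefficients box-averaged),
with truncated box means at the borders so constants are preserved exactly.
ε is interpreted on the [0, 1] intensity scale; volumes are jointly min-max
scaled before filtering and rescaled after, so that the default ε = 0.0016
(= 0.04²) keeps its meaning regardless of attenuation range. Filtering is
applied slice-by-slice along the axial (z) axis. R = 4 and ε = 0.0016 are
the defaults throughout.

The loop: I_initial is the TpV reconstruction; f^(0) = 0; for n = 1..N one
full SART pass from f^(n−1) (λ keeps decaying across outer iterations),
the guidance blend I_guide = I_initial(N−n)/N + f_SART^(n)·n/N, and the
guided filter with input f_SART^(n) and guide I_guide. One inner "SART
reconstruction" means exactly one pass, so the filter acts every pass and
the blend schedule is meaningful.

**Termination.** The loop stops at n = N or once the fused iterate is
quasi-stationary (relative change below tol = 1e−3, measured only on the
iterates — never on any reference). This matters: once the blend weight
shifts far toward the evolving SART image the regularising influence of the
guidance fades, and continuing to iterate past stationarity lets sparse-view
streaks re-enter through the still-relaxed SART passes. The stationarity
criterion halts at the balanced state; in the demo experiment the loop
stops after roughly a dozen outer iterations.

## Metrics

RMSE, PSNR = 10·log₁₀((2^l − 1)²/MSE) and SSIM from global volume moments
with c₁ = (0.01L)², c₂ = (0.03L)², L = 2^l − 1. All shipped data lie in
[0, 1], so l = 1 and PSNR is 10·log₁₀(1/MSE) under either the squared or
unsquared reading of the peak term; for l > 1 the standard squared form is
used. A sliding-window SSIM (scikit-image) is available behind a flag;
global moments are the default because the scalar summary of a whole volume
is what the comparison tables report. Profile curves extract a stated
row/column of a stated slice for reference and reconstruction.

## The demo experiment

`default_demo_config()`: noiseless 64³ head phantom at 1 mm voxels, 32
equispaced views, the geometry above, all five algorithms at a matched
budget of 100 outer iterations (one SART pass ≙ one ADM cycle ≙ one
TpV-GIF outer iteration). 64³ keeps the full five-way comparison around
four minutes on one CPU; the machinery runs unchanged at clinical scale
(256×256×266), which is supported but not exercised by the tests. The
expected behaviour, asserted by the acceptance tests and recomputed by
`scripts/acceptance.py`, is the qualitative ordering
RMSE(TpV-GIF) < RMSE(TpV) < min(SART, SART-TV, ASD-POCS), with PSNR and
SSIM naming the same winner.

## Known limitations

* Circular trajectory and flat panels only; no helical or tilted scans, no
  curved detectors, no polychromatic physics.
* The ℓ_p subproblem uses the one-step generalized shrinkage, not an inner
  iterative refinement; the non-convex problem carries no global-optimality
  guarantee.
* Per-view voxel-sum caching trades memory for speed (one volume per view);
  at clinical scale this cache dominates memory and could be made optional.
* The guided filter window R = 4 is large relative to a 64³ slice (9/64 of
  the width); small interior features are partially averaged at demo scale,
  which shrinks (relatively) at clinical resolution.
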