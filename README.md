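# cbctrec — sparse-angle cone-beam CT reconstruction

Cone-beam CT (CBCT) acquires a full 3-D volume in a single circular scan of
a flat-panel detector, but the X-ray dose scales with the number of view
angles. `cbctrec` is a toolkit for reconstructing CBCT volumes from very few
views (tens instead of hundreds), aimed at people studying iterative and
regularised reconstruction: it implements the classical algebraic and
TV-regularised reconstructors, a total p-variation (TpV) solver, and a
guided-image-filter fusion of the two (TpV-GIF) that combines the edge
retention of algebraic reconstruction with the noise and streak suppression
of non-convex gradient-sparsity regularisation.

## The model

The scan is the linear system **y** = **A x**, where *x* ∈ ℝᴺ holds voxel
attenuation coefficients, *y* ∈ ℝᴹ the measured line integrals, and
*a*ᵢⱼ is the exact intersection length of ray *i* with voxel *j* (computed
matrix-free with Siddon's traversal; forward and back projection are an
exactly matched adjoint pair).

**SART** updates all rays of one view angle φ at a time:

    xⱼ ← xⱼ + λ · Σ_{i∈I_φ} μᵢ aᵢⱼ / Σ_{i∈I_φ} aᵢⱼ ,
    μᵢ = (yᵢ − [Ax]ᵢ) / Σⱼ aᵢⱼ ,

with relaxation λ = 1 decaying by λ_red = 0.99 per full pass.

**TpV** replaces the ℓ₁ norm of total variation with the non-convex ℓ_p
quasi-norm (p = 0.9) of the gradient-magnitude image:

    min ‖∇x‖_p^p   s.t.  y − Ax = e, ‖e‖₂² ≤ ε,  x ≥ 0,

solved by alternating direction minimization: a generalized p-shrinkage
step s_{β,p}(t) = max(t − β^{p−2} t^{p−1}, 0) on the gradient magnitudes, a
linearised data step solved in closed form by 3-D FFT diagonalisation, a
projection of the data error onto the ε-ball, and multiplier ascent.

**TpV-GIF** runs the TpV reconstruction once as the *initial guidance
image*, then iterates: one SART pass, a guidance update that blends the TpV
image and the evolving SART image with weights (N−n)/N and n/N, and a
slice-by-slice guided image filter (window radius R = 4, regularisation
ε = 0.0016 on [0,1]-scaled intensities) that transfers the guidance
structure onto the SART iterate. Early iterations are denoised by the TpV
guidance; late ones are steered by the data-rich SART image.

Reconstructions are scored with RMSE, PSNR and SSIM against ground truth,
plus profile curves and absolute-difference maps.

## Worked example

Simulate a 64³ Shepp-Logan-style head phantom scanned over 32 equispaced
views (source–detector 1040 mm, source–origin 570 mm) and compare all five
reconstructors at a matched budget of 100 outer iterations:

```python
from cbctrec import default_demo_config, run_comparison

result = run_comparison(default_demo_config(seed=1))
for row in result.metrics_rows():
    print(row)
```

prints (about four minutes on one CPU):

```
['algorithm', 'RMSE', 'PSNR', 'SSIM']
['sart',     '0.032649', '29.7226', '0.980309']
['sart-tv',  '0.052136', '25.6573', '0.943046']
['asd-pocs', '0.031856', '29.9362', '0.981253']
['tpv',      '0.030747', '30.2441', '0.983160']
['tpv-gif',  '0.027879', '31.0945', '0.985048']
```

TpV beats every non-fused baseline (lowest RMSE, highest PSNR/SSIM among
SART, SART-TV, ASD-POCS) and the guided-filter fusion improves further on
TpV on all three metrics. SART-TV sits in its characteristic strongly
smoothed regime and trades fine structure away.

The same experiment is available from the shell:

```bash
cbctrec compare --outdir report/          # metrics.csv, profiles, volumes
cbctrec simulate --out proj.h5 --truth gt.mhd
cbctrec reconstruct --algorithm tpv-gif --projections proj.h5 --out rec.mhd
cbctrec evaluate --recon rec.mhd --reference gt.mhd --out metrics.csv
```

Volumes are written as MetaImage (.mhd/.raw) or NIfTI, projections as HDF5
or multi-page TIFF, and every run is reproducible from its saved YAML
config and seed.

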