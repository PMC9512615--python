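# ctdenoise

Hybrid wavelet–bilateral denoising for CT images, with built-in noise
simulation, classic baselines and full-reference quality metrics.

CT slices acquired in clinical settings — dental cone-beam scans in
particular — carry a mixture of Gaussian-like image-domain noise,
signal-dependent speckle and occasional impulse corruption. This package is
for researchers and engineers who want a reproducible, fully synthetic
test bed for such denoisers: it renders the analytic Shepp-Logan head
phantom, injects seeded noise, runs a family of denoising methods behind a
single contract and scores the results.

## The method

The core denoiser (`q5_hybrid`) splits the work by frequency band. For an
image *g = x + n* (or *g = x(1+n)* for speckle), a separable 2D discrete
wavelet transform yields an approximation band *cA* and detail bands
*(cH, cV, cD)* per level. Then:

* **low frequencies** — *cA* is filtered with a bilateral kernel
  *w(i,j,k,l) = exp(−((i−k)² + (j−l)²)/2σ_d²) · exp(−(f(i,j) − f(k,l))²/2σ_r²)*,
  which averages flat regions while leaving strong edges (bone/tissue
  boundaries) intact;
* **high frequencies** — every detail band is shrunk elementwise with a
  threshold function ω_λ chosen from {hard, soft, compromise, improved}.
  The *improved* rule, with adjustment coefficient a ∈ [0, 1], maps
  ω ↦ sign(ω)(|ω| − (1−a)λ) above the threshold and ω ↦ a·ω below it.
  The per-subband threshold λ comes from BayesShrink, λ = σ²/σ_x with
  σ_x² = max(E[ω²] − σ², 0), where the noise scale σ is estimated from the
  finest diagonal band as median(|cD₁|)/0.674;
* the inverse transform reassembles the image, clipped to [0, 1].

Baselines behind the same `denoise(img, config)` contract: universal-threshold
(σ√(2 ln N)) soft wavelet shrinkage (`q1_wavelet`), plain bilateral filtering
(`q2_bilateral`) and non-local means (`q4_nlm`). Metrics: MSE, PSNR
(peak 1.0) and SSIM (11×11 Gaussian window, σ=1.5).

## Worked example

```python
from ctdenoise import NoiseSpec, add_gaussian_noise, denoise, evaluate, generate_shepp_logan

clean = generate_shepp_logan(512)
noisy = add_gaussian_noise(clean, NoiseSpec("gaussian", variance=0.04, seed=7))
before = evaluate(clean, noisy)
after = evaluate(clean, denoise(noisy, method="q5_hybrid"))
print(f"noisy    : MSE={before.mse:.5f}  PSNR={before.psnr:.2f} dB  SSIM={before.ssim:.3f}")
print(f"denoised : MSE={after.mse:.5f}  PSNR={after.psnr:.2f} dB  SSIM={after.ssim:.3f}")
```

prints

```
noisy    : MSE=0.02406  PSNR=16.19 dB  SSIM=0.076
denoised : MSE=0.00608  PSNR=22.16 dB  SSIM=0.237
```

i.e. the hybrid filter removes about three quarters of the squared error
(+6 dB) at this noise level. The `examples/` directory has one short script
per capability (phantom + noise models, hybrid denoising, the benchmark
grid, the shrinkage-function family).

## Command line

```sh
ctdenoise phantom --size 512 --out clean.tiff
ctdenoise addnoise --kind gaussian --variance 0.04 --seed 7 --in clean.tiff --out noisy.tiff
ctdenoise denoise --method q5 --in noisy.tiff --out denoised.tiff
ctdenoise evaluate --ref clean.tiff --test denoised.tiff
ctdenoise benchmark --noise gaussian --methods q1,q2,q4,q5 --out bench/
```

`benchmark` writes a tidy `grid.csv` (one row per noise kind, level, method
and metric with mean/sd over seeds), a `config.lock` provenance file and a
per-cell `run.log`. I/O supports PNG (8/16-bit), float TIFF and read-only
single-slice DICOM.

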