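# Methods

## Scope and model

The package implements a frequency-split denoiser for single-channel CT
images on the [0, 1] intensity scale. The degradation models are additive
Gaussian noise *g = clip(x + n)* with *n ~ N(μ, σ²)*, impulse
(salt-and-pepper) corruption of a fraction *d* of pixels (half to 1.0, half
to 0.0, sites drawn without replacement), and multiplicative speckle
*g = clip(x(1 + n))* with zero-mean Gaussian *n*. Intensities are clipped
to [0, 1] after injection because real grayscale rasters are bounded and
the metrics need a fixed peak; the consequences of that choice are
quantified below.

The hybrid denoiser pipeline is:

1. separable 2D DWT (rows then columns, 2:1 decimation, cascaded on the
   approximation band) with an orthogonal filter;
2. noise scale σ̂ = median(|cD₁|)/0.674 from the finest diagonal band —
   for an orthogonal transform, white noise keeps the same per-coefficient
   σ in every subband, so one estimate serves all bands;
3. every detail subband shrunk elementwise, threshold selected per subband
   by BayesShrink λ = σ̂²/σ_x, σ_x = √max(E[ω²] − σ̂², 0) (λ = max|ω|
   when σ_x = 0, which blanks a signal-free subband);
4. bilateral filtering of the deepest approximation band;
5. inverse DWT, crop to the original shape, clip to [0, 1].

## Shrinkage family

All four rules share the tie convention that |ω| = λ takes the
above-threshold branch, and all are odd functions:

| rule | |ω| ≥ λ | |ω| < λ |
|---|---|---|
| hard | ω | 0 |
| soft | sign(ω)(|ω| − λ) | 0 |
| compromise (a) | sign(ω)(|ω| − aλ) | 0 |
| improved (a) | sign(ω)(|ω| − (1−a)λ) | a·ω |

Compromise interpolates hard (a=0) to soft (a=1); improved reduces to soft
at a=0 and passes sub-threshold coefficients through attenuated, which
preserves faint texture at the cost of keeping a fraction *a* of the
sub-threshold noise. The sub-threshold branch is implemented as the
sign-preserving a·ω; a literal constant-a·λ variant is available via
`ShrinkageRule(small_branch="constant")` for comparison, but it is not the
default because it is discontinuous in ω, breaks odd symmetry, and defeats
the a=0 soft limit.

The universal (fixed) threshold uses the natural logarithm,
λ = σ√(2 ln N), the convention under which it is the near-minimax choice
for N Gaussian coefficients. The MAD scale constant is kept at 0.674
(median of |N(0,1)| to three digits; the difference from 0.6745 is <0.1%).

## Default parameters and the study behind them

Measured on the 512×512 phantom with Gaussian noise at variances 0.02 and
0.10 (the extremes of the benchmark grid), mean PSNR over seeds:

* **wavelet**: db4 — longer filters gain ≤0.1 dB (sym8 +0.07); db4 is kept
  as the common denoising default.
* **levels (hybrid)**: 1. With a single analysis level the approximation
  band still holds a quarter of the noise power and the full anatomy, so
  the bilateral stage does real work; at 3 levels the deep approximation is
  nearly noise-free and the bilateral stage is idle (24.5 dB vs 23.8 dB at
  variance 0.02). The plain wavelet baseline keeps the classic 3 levels.
* **adjustment coefficient a**: 0 for the hybrid default. On this phantom
  the sub-threshold detail coefficients in flat regions are pure noise, so
  any pass-through (a > 0) costs PSNR roughly linearly (a=0.5 loses
  ~2.8 dB). Users denoising texture-rich images should raise a.
* **bilateral on the approximation band**: σ_d = 1.8 px, radius ⌈2σ_d⌉,
  σ_r = 3σ̂. Edges in the approximation band are amplified ×2 per level
  while the noise scale is not, so the range width can exceed the
  image-domain choice without edge loss; 3σ̂ was the plateau of a
  σ_r ∈ [2σ̂, 8σ̂] × σ_d ∈ [1.8, 5] scan.
* **image-domain bilateral baseline**: σ_d = 1.8 px, σ_r = 2σ̂.
* **non-local means baseline**: patch 7, search radius 10, h = 0.8σ̂, with
  the patch distance defined as the patch-averaged squared difference (so
  h lives on the intensity scale).

PSNR uses peak 1.0; SSIM uses the canonical 11×11 Gaussian window with
σ = 1.5, population statistics and C1 = (0.01)², C2 = (0.03)². These match
the scale on which an MSE of 0.0023 corresponds to ≈26.4 dB.

## What the synthetic data does and does not emulate

The Shepp-Logan phantom is piecewise constant with large exactly-flat
regions — ideal for CT geometry tests but much more favorable to
edge-preserving smoothers than real anatomy, which has texture at all
scales. Conclusions about *relative* method ranking on the phantom
therefore favor aggressive smoothers (the plain bilateral filter is
near-optimal at low noise, see Limitations). The noise injectors are
i.i.d. per pixel; real CT noise is correlated by reconstruction and
signal-dependent in the projection domain, neither of which is modeled.

## Numerical choices and degenerate inputs

* Boundary handling: symmetric (half-point) extension for the DWT and
  explicit symmetric reflection for the bilateral/NLM windows, so window
  normalizations never see artificial zeros.
* Perfect reconstruction of an untouched decomposition holds to <1e−8;
  reconstruction is not clipped (clipping is the pipeline's final step).
* σ̂ = 0 (constant images): thresholds collapse to 0 and the shrinkage
  stage is the identity; bilateral σ_r defaults guard with a 1e−6 floor.
* Salt/pepper split: the salt count is the rounded half of the corrupted
  sites; with an odd site count salt gets the extra pixel.
* Requests for more decomposition levels than the image/filter allow fail
  with the maximum feasible level in the message.

## Residual-bias floor under clipping

Clipping noisy intensities to [0, 1] makes the conditional mean of the
noisy image a biased estimate of the clean one wherever the clean value is
within ~3σ of a boundary — on this phantom, the entire background (x = 0).
No denoiser can remove this smooth bias. Measured at 512²: the bias-only
MSE is 0.0022 at variance 0.02 (a 26.6 dB PSNR ceiling) and 0.0115 at
variance 0.10 (19.4 dB ceiling). The hybrid method reaches 24.5 dB and
18.6 dB respectively, i.e. within ~2 dB and ~0.8 dB of those ceilings.

A related caveat applies to validating injected noise variance: at
variance 0.04 every [0, 1] intensity lies within 2.5σ of a clip boundary,
so even "unclipped" residuals follow a truncated normal; the test suite
checks the injector against the exact truncated-normal variance rather
than the nominal one.

## Known limitations

* **Impulse noise**: coefficient shrinkage plus bilateral averaging is the
  wrong tool for salt-and-pepper corruption — impulses spread across all
  subbands and survive partially (MSE ≈ 0.032 at 10% density versus 0.044
  uncorrected). A rank/median-type prefilter would be needed; none is
  included because the hybrid pipeline is the package's subject.
* **SSIM on flat phantoms**: small residual high-frequency noise in the
  large flat background dominates the local structure terms, so SSIM stays
  low (~0.25 at variance 0.02) even when PSNR is near its ceiling; SSIM on
  this phantom mostly measures residual noise, not edge fidelity.
* **Bilateral baseline at low noise**: on the piecewise-constant phantom
  the plain bilateral filter is extremely strong, and at variance 0.02 it
  edges out the hybrid method by ~0.4 dB; from variance 0.04 upward the
  hybrid leads. On textured images the ordering at low noise can differ.
* The dual-tree complex wavelet baseline is not implemented; an external
  implementation can be attached with `register_method` and then
  participates in benchmark grids.
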