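# Methods

## Color conversions

8-bit sRGB values are scaled by 1/255 and decoded with the IEC 61966-2-1
piecewise companding (linear segment below 0.04045, exponent 2.4 above);
a pure 2.2 gamma is *not* used. Linear RGB maps to CIE XYZ through the
standard sRGB primaries matrix, column-normalized so that (255,255,255)
lands exactly on the configured white point. The default white is D65 with
the 2° observer (Xn=0.95047, Yn=1, Zn=1.08883), the white sRGB is referenced
to; it is configurable (`WhitePoint`) but no chromatic adaptation transform
is applied — the package targets 8-bit camera output, not ICC-managed
workflows.

CIELAB and CIELUV follow the CIE 1976 definitions with the cube-root
function and its linear segment below (6/29)³; L* is on the 0–100 scale and
identical between the two spaces (both derive from Y alone). Degenerate
cases are pinned by convention: XYZ = 0 maps to Lab = Luv = (0,0,0) (the
u′,v′ chromaticities are undefined at black), and achromatic pixels (C = 0)
carry hue h = 0 in LCh so no NaN can reach the CMC/CIEDE2000 hue terms. All
arithmetic is float64 regardless of input dtype.

## Metrics

All six metrics are evaluated pixel-wise and vectorized; the first argument
is always the reference image.

* **Euclidean ΔE** operates directly on the 0–255 integer scale, so its
  values can exceed 255 (max 255√3 ≈ 441.7).
* **CIE94** uses ΔC = C₁ − C₂, recovers the hue term from
  ΔH² = Δa² + Δb² − ΔC² (clamped at 0 before the square root), and weights
  with S_C = 1 + k₁C₁ (reference chroma) and S_H = 1 + k₂C₂ (sample
  chroma). Presets: graphic arts (k_L=1, k₁=0.045, k₂=0.015) and textiles
  (k_L=2, k₁=0.048, k₂=0.014). This per-argument weighting makes the
  formula asymmetric under swap; `MetricParams(cie94_symmetric=True)`
  substitutes √(C₁C₂) in both weights for users who need a symmetric
  variant (off by default). The k₁=k₂=0 limit reduces exactly to CIE76(Lab),
  which the tests exploit as an algebraic oracle.
* **CIEDE2000** is the canonical formula: chroma rescaling a′ = a(1+G) with
  the 25⁷ constant, primed hues from atan2(b, a′) folded to [0,360), hue
  differences folded into (−180, 180], ΔH′ = 2√(C₁′C₂′)·sin(Δh′/2), the
  four-term hue weighting T, Δθ = 30·exp(−((h̄′−275)/25)²),
  R_C = 2√(C̄′⁷/(C̄′⁷+25⁷)), R_T = −sin(2Δθ)·R_C, and S_L centered at
  L* = 50. Δh′ is defined as 0 when either chroma vanishes. The
  implementation reproduces the published 34-pair reference vector suite to
  1e-4 and an independent scalar implementation to 1e-9.
* **CMC l:c** anchors every weight on the reference: S_L = 0.511 for
  L₁ < 16 and 0.040975·L₁/(1+0.01765·L₁) otherwise;
  S_C = 0.0638·C₁/(1+0.0131·C₁) + 0.638; S_H = S_C(F·T + 1 − F) with
  F = √(C₁⁴/(C₁⁴+1900)) and the hue factor
  T = 0.56 + |0.2 cos(h₁+168°)| for h₁ ∈ [164°, 345°] (boundaries
  inclusive), T = 0.36 + |0.4 cos(h₁+35°)| otherwise. The absolute-value
  bars on T and the square root in F are load-bearing: without them S_H can
  reach zero or below for moderately chromatic references near h₁ ≈ 145°,
  which would break the positivity of the tolerance semi-axes. The hue term
  is recovered from the chord, ΔH² = 2C₁C₂(1 − cos Δh), clamped at 0.

Quantities under square roots are clamped at zero throughout; hue branch
comparisons are done in degrees with inclusive boundaries.

## Difference-map I/O

Input images must be 8-bit RGB (JPEG/PNG/TIFF); grayscale and 16-bit inputs
are rejected, alpha channels stripped with a warning. Pairs must already be
co-registered — a dimension mismatch aborts with a pointer to external
registration tools rather than attempting any resampling.

Outputs per pair: a plain-text float matrix (row-major, tab-separated,
6-decimal fixed point, LF endings — a fixed dialect so regression tests can
compare bytes) and an 8-bit single-channel uncompressed TIFF holding
round-half-up(clamp(ΔE, 0, 255)). The 8-bit image is deliberately *not*
min-max rescaled: clamping keeps gray levels comparable across image pairs,
at the cost of saturating Euclidean values above 255. A display-only
`--normalize` option rescales min→0/max→255.

## Perturbation protocol

"Reduce channel c by fraction f" is read multiplicatively:
v → round(v·(1−f)), half away from zero, clamped to [0,255]. The
multiplicative reading scales with each pixel's intensity and leaves zeros
fixed; an `absolute` mode (v → round(v − f·255)) implements the alternative
flat-offset reading. The study grid is f ∈ {0.02, 0.05, 0.10} × channel ∈
{R, G, B}: 9 altered images per base, 27 for a trio, 162 error matrices
under six metrics. The module is fully deterministic.

## Synthetic slides

The generator emulates stained brightfield slides: a neutral near-white
background (234 on all channels), 40 soft-edged elliptical blobs (Gaussian
rim, flat core) with semi-axes 4–13 % of the image side, and 2 %
multiplicative shading noise shared across channels (preserving hue). Blob
colors put the dominant channel in 160–186 and the other two in 128–154;
the ranges are disjoint, so the dominant channel's mean strictly exceeds
the others whenever any blob is drawn. Each trio image gets seed + channel
index, so layouts differ while the palette construction is shared.

Two design choices matter downstream:

* **Texture, not gradients.** Blob compositing plus noise gives error
  histograms with non-trivial skewness/kurtosis/entropy, so all five
  statistics carry information.
* **Intensity-matched trio.** The linearity analysis pools the trio per
  channel (9 points per regression), and the pooled fit is only as linear
  as the trio's per-channel means are homogeneous: the mean Euclidean error
  under a fraction-f reduction of channel c is ≈ f·mean(c), so
  between-image spread in mean(c) appears as residual variance growing with
  f. The narrow, disjoint palette bounds the dominant-vs-other image-mean
  gap to ~14 gray levels, which keeps the pooled Euclidean R² above 0.99 —
  the regime of three comparably stained, comparably exposed slides that
  the benchmark is meant to probe. Real slide sets with strongly different
  stain loads would show lower pooled R² for *every* metric; per-dataset
  regressions would then be the right grouping.

What the generator does **not** emulate: real stain co-localization
(hematoxylin/eosin deconvolution structure), optical blur and vignetting,
chromatic aberration, compression artifacts, and the very bright saturated
background of real slide scanners. Passing benchmarks on synthetic trios
therefore demonstrates the pipeline's correctness and the metrics'
*relative* behavior under controlled perturbations, not their ranking on
any particular real dataset. In particular, published comparisons on real
microscopy slides report CIE76(Lab) and CMC as distinctly non-linear
(R² ≈ 0.1) on bright-background slides; on the homogeneous synthetic trio
every metric is fairly linear and that dramatic separation does not appear.
Reproducing it requires the original slide images and is a qualitative,
non-gated check.

## Statistics

Histogram statistics default to the **quantized** 8-bit error image — the
thing the grayscale output actually shows — with a `float` domain option.
Moments are population moments; kurtosis is excess (Fisher); entropy is
Shannon entropy in bits of the 256-bin histogram with 0·log 0 = 0, hence in
[0, 8]. A constant matrix has variance 0 and, by convention, skewness =
kurtosis = entropy = 0 rather than NaN.

PCA z-scores the five statistics column-wise (dropping zero-variance
columns with a warning), uses a full SVD, and fixes each component's sign so
its largest-magnitude loading is positive; scores are labeled by metric and
a per-metric mean pairwise distance quantifies cluster openness.
Correlation grids are Pearson over the five statistics plus the fraction;
correlations involving a constant column are reported as 0 with a warning.

Linearity regressions are ordinary least squares of a statistic on the
fraction expressed in percent, pooled over base images per metric ×
channel (scipy's `linregress`: slope, intercept, R² = squared Pearson r,
two-sided Wald t test on the slope, and 95 % t-based confidence margins on
both coefficients). A constant response returns slope 0, R² 0, p 1. The
summary table averages, per metric, the R² of the mean- and
variance-regressions and the slope/intercept (with margins) of the mean
regressions over the three channels.

## Problem sizes and determinism

The benchmark's study scale is a 256×256 trio — 162 error matrices, a few
seconds end to end — which is where the test suite and the acceptance
script run it; the generator accepts any size ≥ 8. All randomness flows
from explicit `numpy.random.default_rng(seed)` generators (no global
state), so benchmark reruns with the same seed reproduce every CSV byte for
byte, and the text/TIFF outputs round-trip bit-exactly.

## Known limitations

* No ICC profiles, >8-bit or wide-gamut input, or chromatic adaptation.
* No image registration: misaligned pairs are the user's problem, by design.
* CIE94 and CMC are implemented in their reference-anchored (asymmetric)
  form; symmetry-requiring applications should use the symmetrized CIE94
  switch or a symmetric metric.
* The 8-bit map clamps at 255; Euclidean ΔE of extreme pairs saturates in
  the TIFF (the text matrix keeps the full float values).
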