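# Methods

This note documents the model, the numerical choices, and what the synthetic
calibration does and does not establish.

## Wavelet transform

The analyzing wavelets are the partial derivatives ψ₁ = ∂φ/∂x, ψ₂ = ∂φ/∂y of
an isotropic 2D Gaussian φ. The transform at position **b** and scale *a* is
the a⁻²-normalized correlation with the dilated wavelets, equal (up to sign)
to *a*·∇(G_a ∗ f) where G_a is the unit-mass Gaussian of standard deviation
*a* pixels. We orient the sign so the argument points *uphill* — along the
gradient of the smoothed image — which is the convention the linear-ramp
behavior implies (a ramp rising in +x has argument 0). The anisotropy factor
is invariant to this sign choice (a global π rotation of all angles) and to
any global rescaling of the modulus, including the a⁻² prefactor itself.

- **Scale convention.** The Gaussian's σ equals the scale parameter *a* in
  pixels. The source method does not separate σ from *a*; this is the
  documented assumption.
- **Implementation.** Fourier domain (`scipy.fft.rfft2`), with analytic
  multipliers i·a·k_x·exp(−a²|k|²/2) (and k_y). Boundary handling is
  therefore periodic; the central-crop analysis (below) is the edge-robust
  alternative. A direct-space brute-force convolution oracle confirms the
  Fourier path to ~1e−9 relative at σ = 2.5 on 32² rasters (test tolerance
  1e−6).
- **Default ladder.** 50 geometrically spaced scales from 7 to 210 px. At
  0.3516 μm/px (a 180 μm field of view sampled at 512 px) this spans
  ≈ 2.5–73.8 μm. The count and spacing are configurable; nothing downstream
  assumes a particular density.
- **Angles** live on the half-open circle [−π, π); the single atan2 output
  +π is folded to −π so the histogram bins tile the circle exactly.

## Modulus maxima and chains

A pixel is retained iff its modulus is ≥ the bilinearly interpolated modulus
at unit distance on *both* sides along its own gradient direction, with
strict inequality on at least one side. Rationale for the tie rule: discrete
single-pixel-wide ridges survive, exactly flat plateaus (e.g. constant
images) are discarded. Probes wrap periodically, consistent with the FFT
transform. No modulus or chain-length threshold is applied by default (a
`min_length` filter exists, off by default).

Chains are 8-connected components of the retained pixels, merged across the
periodic seam by union-find. The within-chain ordering is a depth-first
traversal from an endpoint; it is reported for display only and carries no
meaning downstream.

## Angle PDFs and the anisotropy factor

Histogram bins are half-open [A_i, A_i + ΔA) with A₀ = −π, ΔA = 2π/N_bins;
densities are count/(n·ΔA) and integrate to 1 (enforced to 1e−9). The
anisotropy factor sums one term per bin, i = 0 … N_bins−1 (a printed
N_bins+1-term bound would double-count −π ≡ π; only the N_bins-term sum
reproduces the analytic values Fa = 0 for a flat PDF and 2·(1 − 1/N_bins)
for a single-bin delta).

- **Fixed binning**: N_bins = 64 by default.
- **Variable binning**: N_bins = max(min_bins, ⌊n/samples_per_bin⌋) with
  samples_per_bin = 100 and min_bins = 4. The floor prevents degenerate 1–2
  bin PDFs at the largest scales where maxima are scarce.
- **Binned unit**: one angle per WTMM *point* by default. The source
  phrasing is ambiguous between points and chains; a per-chain circular-mean
  mode (`unit="chain_mean"`) is provided for sensitivity analysis.
- Scales with no maxima are recorded as missing (NaN, n = 0), warned about,
  and excluded from ensemble aggregates — never imputed.

Why variable binning stabilizes Fa: for an isotropic image with n angle
samples in N bins, the sampling noise floor of Fa scales like √(N/n), and its
across-image coefficient of variation shrinks with the number of bins; fixing
n/N = 100 makes both roughly scale-independent, with the largest effect at
small scales where n is huge and 64 bins are needlessly coarse.

## Calibration analyses

- **Isotropic references.** White noise (i.i.d. N(0,1) pixels) and
  fractional Brownian surfaces synthesized by Fourier filtering: shape the
  FFT of real white noise by |k|^−(H+1) (power ∝ |k|^−(2H+2)), zero the DC
  coefficient, invert. H defaults to 0.5 (the ordinary Brownian surface; the
  source does not state its exponent). Filtering a *real* noise field keeps
  the spectrum Hermitian, so the output is real to machine precision and
  bit-reproducible given the seed.
- **Normalization** of an image's Fa curve by the per-scale *median* Fa of a
  white-noise ensemble is a ratio by default (a subtraction mode exists);
  the original presentation does not state which, so this is a documented
  package choice.
- **Central-crop analysis**: transform and detection run on the full (e.g.
  1024²) image; only maxima inside the centered crop (e.g. 512²) window are
  binned, truncating straddling chains. This isolates FFT boundary
  contamination: crop curves reproduce native-size white-noise Fa within
  sampling error (3 MADs per scale at 20 replicates).
- **Coefficient of variation** across an ensemble uses the sample SD
  (ddof = 1) over the mean, per scale, requiring ≥ 3 curves.

## Group statistics

Per-scale medians over curves with a value at that scale, and a two-sided
Wilcoxon rank-sum test per scale on the per-image Fa values. The exact null
distribution is used for combined n ≤ 30 without ties; otherwise the
tie-corrected normal approximation with a continuity correction clamped at
z = 0, so identical groups give p = 1 exactly. Raw p-values are reported
(matching the conventional per-scale presentation against the 0.05 line);
Benjamini–Hochberg adjustment is available by flag. The crossover scale
between two median curves is the geometric mean of the ladder scales
bracketing the first sign change of their difference — an artifact
convention for reading off the scale where group ordering reverses.

Each image is treated as one independent observation; patient- or
slide-level clustering is out of scope and should be handled upstream if
images are nested.

## Synthetic data: what it does and does not establish

The generators state the calibration world: 512² rasters (136 per type in
the original study; 30 per type in the test suite for runtime, with the
count configurable), white noise and H = 0.5 Brownian surfaces, and an
oriented sinusoidal grating as a known-anisotropic positive control. The
grating's wave vector is snapped to the raster's integer frequency grid so
it is exactly periodic — without snapping, the wrap discontinuity injects
broadband power that swamps the grating response at scales beyond its
wavelength. None of these emulate SHG optics, detector noise, or the spatial
intermittency of real collagen; a green calibration suite establishes the
*method's* behavior on stationary (an)isotropic fields, not performance on
tissue.

A finite-wavelength grating carries directional signal only while
exp(−(2πa/λ)²/2) exceeds the ~1e−16 synthesis noise floor, i.e. up to
a ≈ λ·√(73)/2π ≈ 1.4·λ. Positive-control tests therefore use λ = 64 px with
scales up to 64 px (signal/noise margin ≈ 5·10⁷ at the top scale).

## Known limitations

- **Large scales on periodic rasters.** For σ ≳ 0.25 × image side, the
  Gaussian envelope leaves only the lowest Fourier mode shells, and the Fa
  distributions of *any* stationary Gaussian fields converge to the same
  few-mode angle statistics: white-noise and Brownian ensembles become
  statistically indistinguishable (per-scale rank-sum p ≈ 0.4–0.9 at n = 30,
  512², scales ≥ 138 px), so their median ordering is undefined there. The
  calibration ordering (white noise below Brownian) is robust at all scales
  up to ~0.25 × side. Practical guidance: keep the largest scale at or below
  a quarter of the image side, or analyze a larger image and use the
  central-crop curve.
- Non-square images are rejected, not padded; the FFT and ladder
  conventions assume square rasters.
- Intensities are used verbatim (the method is affine-invariant); no
  background subtraction or flat-fielding is performed.
- The pipeline analyzes each scale independently; no scale-space linking of
  maxima (WTMM skeleton) or multifractal partition functions.
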