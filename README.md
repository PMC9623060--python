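# wtmm-aniso

Multiscale anisotropy analysis of grayscale images with the 2D Wavelet
Transform Modulus Maxima (WTMM) method — built for quantifying the
directional organization of fibrillar textures such as collagen in
second-harmonic-generation (SHG) microscopy, across a continuous range of
size scales rather than at a single resolution.

## The method

At each scale *a* (in pixels) the image *f* is convolved with the two partial
derivatives of an isotropic 2D Gaussian, yielding a smoothed gradient field

```
T_ψ[f](b, a) = a · ∇ (G_a ∗ f)(b),     M = |T_ψ|,   A = arg(T_ψ)
```

The **modulus maxima** (WTMM) are the pixels where *M* is locally maximal
along the direction of the argument *A* — they trace the intensity edges of
the image at that scale, and organize into connected *maxima chains*. The
angles *A* of all WTMM points at one scale are histogrammed into a
probability density P_a(A) over [−π, π), and the **anisotropy factor**

```
Fa(a) = Σ_i |P_a(A_i) − 1/2π| · ΔA,     ΔA = 2π / N_bins
```

measures the L1 departure of the edge-direction statistics from isotropy:
Fa = 0 for a perfectly flat PDF, with supremum 2 (a single-bin delta gives
2·(1 − 1/N_bins)).

Two refinements are included:

- **Variable binning** — instead of a fixed bin count (conventionally 64),
  the bin count at each scale is chosen so that each bin holds ~100 samples,
  stabilizing the noise floor of Fa across scales where maxima counts differ
  by orders of magnitude.
- **White-noise calibration** — ensembles of synthetic isotropic fields
  (i.i.d. Gaussian white noise; fractional Brownian surfaces via Fourier
  filtering) establish the per-scale isotropic reference; Fa curves are
  normalized by the white-noise median so that values > 1 indicate genuine
  directional structure.

Group comparisons follow the field's standard presentation: per-scale median
Fa curves per image group and a two-sided Wilcoxon rank-sum test at each
scale.

## Worked example

```python
import numpy as np
from wtmm_aniso import (FieldSpec, generate_field, make_scale_ladder,
                        BinningPolicy, multiscale_curve)

ladder = make_scale_ladder(7, 64, 6, pixel_size_um=180 / 512)
policy = BinningPolicy(mode="variable")  # 100 maxima per bin

noise = generate_field(FieldSpec(512, "white_noise", seed=1))
fibers = generate_field(FieldSpec(512, "oriented_stripes",
                                  orientation_deg=30.0, wavelength=64, seed=1))

for name, image in [("white noise", noise), ("oriented texture", fibers)]:
    curve = multiscale_curve(image, ladder, policy, image_id=name)
    print(name)
    for s_px, s_um, fa, n in zip(curve.scales_px, curve.scales_um,
                                 curve.fa, curve.n_samples):
        print(f"  a = {s_px:5.1f} px ({s_um:4.1f} um)  n_maxima = {n:6d}  Fa = {fa:.3f}")
```

prints

```
white noise
  a =   7.0 px ( 2.5 um)  n_maxima =  21362  Fa = 0.108
  a =  10.9 px ( 3.8 um)  n_maxima =  13746  Fa = 0.146
  a =  17.0 px ( 6.0 um)  n_maxima =   8837  Fa = 0.187
  a =  26.4 px ( 9.3 um)  n_maxima =   6018  Fa = 0.311
  a =  41.1 px (14.5 um)  n_maxima =   3599  Fa = 0.526
  a =  64.0 px (22.5 um)  n_maxima =   2190  Fa = 0.381
oriented texture
  a =   7.0 px ( 2.5 um)  n_maxima =   9216  Fa = 1.957
  a =  10.9 px ( 3.8 um)  n_maxima =   9216  Fa = 1.957
  ...
```

The isotropic field shows a small, slowly rising Fa (the finite-sample noise
floor grows as maxima become scarce at large scales), while the oriented
grating sits near the theoretical supremum at every scale. Normalizing the
texture's curve by a white-noise ensemble median (``normalize_by_reference``)
turns these into ratios ≫ 1.

## Command line

```
wtmm-aniso generate  --kind brownian_surface --side 512 -n 30 --seed 0 --out-dir calib/
wtmm-aniso analyze   images/*.tiff --pixel-size-um 0.3516 --out curves.csv
wtmm-aniso calibrate -n 30 --side 512 --out reference.csv
wtmm-aniso compare   --curves curves.csv --out-dir results/ --plot
wtmm-aniso run       --config run.yaml --seed 1 --out results/
```

`run` drives the whole batch pipeline from a YAML/TOML config (labelled image
groups or synthetic ensembles, scale ladder, binning policy, white-noise
reference) and writes per-image curves, group medians, pairwise per-scale
p-value tracks and a JSON manifest; outputs are byte-identical for identical
config + seed.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the method's analytic anchor values from scratch through the
package's own PDF/Fa routines: the supremum of the anisotropy factor
(single-bin delta PDFs at 64/1024/65536 bins, extrapolated in 1/N_bins) and
the Fa of an exactly uniform angle PDF, writing both to the JSON file given
by `--out`.
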