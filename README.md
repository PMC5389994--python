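# beefield

Bee-eye analysis of multispectral flower images: photoreceptor responses,
per-region signal-to-noise ratios, and the null-model factor sweep that
explains why the long-wavelength (green) receptor channel carries the most
reliable signal about flowers.

## The problem

Bees are trichromats — short- (S, λmax ≈ 344 nm), medium- (M, ≈ 436 nm) and
long-wavelength (L, ≈ 544 nm) photoreceptors — yet they use the L channel
almost exclusively for edge detection, motion and fine-scale target
detection. One adaptive explanation: across natural flower scenes, L-receptor
responses are the most *consistent*, both across flower species and within
a single petal, leaf, or flower center. This package implements the modelling
chain needed to quantify that claim on multispectral imagery (7 co-registered
grayscale bands, peak transmissions 340–700 nm in 60-nm steps, with an
in-frame gray-reference strip), plus a synthetic-scene generator with full
ground truth so that every stage is testable without the original photographs.

## The model

For each receptor with spectral sensitivity S(λ), illuminant D(λ), stimulus
reflectance I_s(λ) and adaptation background I_B(λ), all sampled on the
7-band grid:

    P = R · Σ_λ I_s(λ) S(λ) D(λ)         quantum catch
    R = 1 / Σ_λ I_B(λ) S(λ) D(λ)         von Kries sensitivity factor
    E = P / (P + 1)                       normalized response, E ∈ [0, 1)

The sensitivity factor pins the adaptation background (the "average leaf")
at P = 1 and E = 0.5 exactly, and cancels any rescaling of the illuminant.
Per image region (petal / center / leaf), 1000 random pixels are pushed
through this chain; the region's signal-to-noise ratio per receptor is
SNR = mean(E) / SD(E), a within-object homogeneity measure. The null-model
sweep replaces each component (illuminant, background, sensitivity shape,
reflectance statistics) with a unit version in all 16 combinations and sweeps
the receptor peak across the 7 bands to show which factors produce the
L-channel advantage.

Receptor sensitivities default to an A1 visual-pigment template (alpha band
after Govardovskii et al. 2000, plus a UV beta band that grows with peak
wavelength); measured sensitivities can be supplied as CSV.

## Worked example

```python
import beefield as bf

# 30 synthetic flower species -> white balance -> band alignment ->
# leaf-adapted receptor responses -> per-region SNR statistics
res = bf.run_synthetic_study(k=30, n_pixels=1000, seed=1)
for rc in ("petal", "center", "leaf"):
    row = {r: round(res.summary.cell(rc, r, "snr")[0], 1) for r in "SML"}
    print(rc, row)
```

prints

```
petal {'S': 5.7, 'M': 18.6, 'L': 31.4}
center {'S': 1.7, 'M': 4.6, 'L': 8.0}
leaf {'S': 1.9, 'M': 5.8, 'L': 10.2}
```

Reading: in every region class the L channel has the highest SNR (its broad
sensitivity integrates several bands, averaging out pixel noise, and flowers
reflect more long-wavelength light), and petals — large, smooth, homogeneous
surfaces — give several-fold better signal than leaves or centers. These are
the two signatures the receptor-level account of L-channel dominance rests
on. `res.reports` carries the Kruskal–Wallis and pairwise Wilcoxon
signed-rank comparisons of the three channels.

The same chain runs on real imagery from a directory of stack manifests:

```python
res = bf.run_database("path/to/flower_db", n_pixels=1000, seed=1)
```

A `beefield` CLI wraps the common tasks: `beefield synth` (generate scenes),
`beefield render --mode bee|human` (false color), `beefield respond`
(response heat maps), `beefield sample` (region statistics CSV),
`beefield sweep` (the 16-configuration factor table).

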