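# specresolve

Gradient-based background removal for spectrally resolved fluorescence
microscopy of probes with narrow, well-defined emission bands
(FWHM < 20 nm) — most notably the f–f emission lines of lanthanide ions
such as Eu(III) and Tb(III).

## The problem

In a spectral image every pixel holds a full emission spectrum S′ (here:
a 10×10 raster, 1340 CCD channels per pixel). The specific signal from a
lanthanide probe sits as a handful of very narrow lines on top of a broad,
bright autofluorescence/dye background, so simple contrast enhancement
(subtracting a constant threshold *T*, giving X = max(S′ − T, 0)) can never
remove the structured background. Because the probe lines are dramatically
*sharper* than anything else in the spectrum, their presence is perfectly
legible in the spectral gradient — and that is what both methods here use.

After Savitzky–Golay smoothing (S′ → S), differentiation (Δpixel = 1) and a
second smoothing pass, each pixel has a gradient signal Δ:

* **Method I** maps sharp-feature contrast directly as L(I) = |Δ|, summed
  over a spectral window. Fast, but not photon-quantitative.
* **Method II** thresholds Δ at ±T1 to pin *anchor points* at the onset and
  end of every sharp feature, merges anchors closer than T2 (in cm⁻¹, so a
  multiplet of vibrational sub-bands counts as one feature), discards the
  long-pass filter edge with a width threshold T3, and then builds a
  per-pixel baseline

      B = S            between an end anchor and the next onset anchor,
      B = straight line between an onset anchor and the next end anchor,

  and resolves the probe signal as **L = max(S − B, 0)**. Between features
  B equals the data, so the resolved background is *exactly zero*: the
  signal-to-background ratio of an L(II) image is infinite, and every
  photon in L is attributable to the narrow-band probe. Optional cleanups:
  spectra with a resolved total below T4 are zeroed, and features whose
  gradient exceeds `cosmicthres` are treated as cosmic rays and absorbed
  into the baseline. Defaults: T1 = 5, T2 = 200 cm⁻¹, T3 = 40 channels,
  T4 = 2000 counts, cosmicthres = 500.

No external data are needed: a phantom generator reproduces the benchmark
sample (broad dye background, lanthanide-doped particle disc, 532 nm
long-pass edge, cosmic rays, Poisson noise) together with exact ground
truth for every test.

## Worked example

```python
import dataclasses
import specresolve as sr

cfg = dataclasses.replace(
    sr.default_phantom_config(seed=1, noise="none"), cosmic_ray_rate=0.0
)
cube, truth = sr.generate_phantom(cfg)

rc = sr.resolve_cube(cube, sr.MethodIIParams(), method=2)
image = sr.integrate_image(rc.resolved)
print("signal-to-background:", sr.signal_to_background(sr.diagonal_profile(image)))

gate = sr.SpectralGate("Eu", 605.0, 626.0)   # the 612/618 nm doublet
report, summary = sr.recovery_report(truth, rc.resolved, [gate])
print("gated recovery:", summary["Eu"])
```

prints

```
signal-to-background: 1.59e+04:0 (infinite contrast)
gated recovery: {'bias': -320.53227411471926, 'rmse': 320.5322741147193,
                 'false_positive_background_pixels': 0, 'background_pixels': 79}
```

The diagonal intensity profile of the resolved image has a maximum of
~1.6·10⁴ counts inside the particle footprint and is exactly 0 in every
background pixel, so the ratio is reported as infinite contrast. Gated on
the Eu 612/618 nm doublet, the recovered per-pixel areas sit ~3% below the
generator's ground-truth line areas (the straight-chord baseline clips the
sub-threshold line tails), with zero false-positive background pixels.

The same pipeline is scriptable from a shell:

```sh
specresolve phantom --seed 1 --out ph
specresolve resolve --input ph/cube.csv --method 2 --out res
specresolve image   --input res/l_cube.csv --gate eu_616:605:626 --out img/eu.tiff
specresolve profile --input img/eu.tiff --diagonal --out prof/diag.csv
```

Every subcommand writes a `manifest.json` (version, parameters, seed,
input checksums) beside its outputs.

The two methods are also exposed as sklearn-style transformers
(`AnchorBaselineResolver`, `GradientContrast`) that map a matrix of raw
spectra `(n_spectra, n_channels)` to resolved signals of the same shape and
compose with sklearn pipelines.

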