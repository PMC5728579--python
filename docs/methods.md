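# Methods

## Signal model

Each pixel of a spectral image holds a raw emission spectrum S′ of N
detector channels (default N = 1340) with a strictly increasing
channel→wavelength calibration. The measured spectrum is modelled as a sum
of (i) broad fluorophore background (FWHM ≥ 50 nm), (ii) narrow probe
lines (FWHM < 20 nm; lanthanide f–f transitions are typically a few nm),
(iii) the transmission edge of a long-pass emission filter, (iv) sparse
cosmic-ray spikes of one or two channels, and (v) Poisson counting noise.
The discriminating assumption is purely about *sharpness*: off the narrow
lines the smoothed spectral gradient stays within ±T1, while every real
probe line crosses it. Nothing about specific line positions is assumed —
no per-lanthanide anchor templates — which is what keeps the method usable
for multi-probe labelling.

## Processing pipeline

1. Savitzky–Golay smoothing S′ → S (window 9 channels, order 2 by
   default), polynomial-fit edge evaluation, no padding.
2. Gradient Δy/Δx with Δpixel = 1: central differences at interior
   channels, one-sided at the two ends.
3. The gradient is smoothed again with the same filter, giving Δ. The
   channel-domain gradient is used throughout; a wavenumber-domain gradient
   behaves very similarly on calibrated data and is not implemented.
4. Method I: L(I) = |Δ|, with channels above an optional gradient ceiling
   zeroed (cosmic rays), integrated over a window (whole range by default;
   a window past the filter onset avoids the filter's own contribution).
5. Method II marker coding at threshold T1 (strict comparisons):
   d1 ∈ {−1, 0, 1} codes Δ against ±T1; every 0 adjacent to a nonzero d1
   becomes 2 in d2; d3 is the first difference of d2 (0 prepended) with
   all values other than ±2 deleted. +2 marks a feature onset, −2 an end.
6. Cleanup: of consecutive equal markers, the leftmost +2 / rightmost −2
   survives; end→onset pairs closer than T2 in wavenumber are eliminated
   pairwise, left to right with re-evaluation, merging vibrational
   sub-bands of one electronic transition into a single feature.
7. Channel 1 is prepended as a terminal "end" anchor and channel N
   appended as a terminal "onset" anchor. The first feature pair is then
   checked against T3: narrower than T3 channels it is the filter edge and
   is dropped; wider (a band overlapping the edge) its onset anchor is
   relocated to the channel before the band maximum where S is minimal but
   still above S at the band's end (ties broken toward the band), making
   the chord under that band as horizontal as possible.
8. Baseline: B = S on every end→onset interval; on each onset→end interval
   B is the straight line through S at the two anchors, interpolated on
   the open interval (B = S at the anchors themselves). The resolved
   signal is L = max(S − B, 0).
9. Optional cleanups, in this order: features containing |Δ| >
   `cosmicthres` are dropped from the anchor set before baseline building
   (the spike is absorbed into B and excluded from L); afterwards, if the
   total of L is below T4 the whole spectrum's L is zeroed. T4 is applied
   to the resolved total (not the raw total): residual cosmic fragments and
   noise-born micro-features produce small resolved totals, which is
   exactly what the threshold is meant to kill.

## Parameters

| parameter | unit | default | role |
| --- | --- | --- | --- |
| T1 | Δcounts/Δpixel | 5 | gradient threshold separating sharp features from background; too low turns noise into features, too high misses band onsets. Scale with photon noise (√signal) for much brighter data. |
| T2 | cm⁻¹ | 200 | minimum end→onset gap; closer pairs are merged so one electronic transition with vibrational structure counts as one feature |
| T3 | channels | 40 | maximum width of the filter-edge feature; optional (None disables for filter-free instruments) |
| T4 | counts | 2000 | minimum resolved total; dimmer spectra are zeroed (optional) |
| cosmicthres | Δcounts/Δpixel | 500 | gradient ceiling above which a feature is a cosmic ray (optional; must exceed T1) |
| SG window / order | channels / – | 9 / 2 | smoothing used both before and after differentiation; preserves lines of FWHM ≳ 4 channels |

The same smoothing settings are used at the pre- and post-differentiation
passes; they are independent in principle but there is no evidence a split
setting helps, and a single bundle keeps the parameter space small.

## Anchor-set edge cases

Anchors alternate end/onset starting and finishing with the terminal
anchors, so a regular spectrum yields an even-length alternating list. Two
irregular cases are handled explicitly. A feature still rising at the last
channel leaves a trailing onset marker; the terminal anchor at N then
closes that feature (odd-length list, the final interval is interpolated).
A feature already decaying at channel 1 leaves a leading end marker with
no onset; it is dropped with a warning and the region is treated as
background. Anything else non-alternating is degenerate: the pixel falls
back to the no-feature anchors [1, N] (B = S, L = 0) with a warning, and
cube-level processing continues.

## Phantom generator

The generator emulates the benchmark sample the method was developed on: a
polymer film stained with three broad-band dyes (fluorescein-like 525/60 nm
at 150 counts, MitoTracker-like 600/55 nm at 60, ATTO647N-like 665/55 nm at
40), a disc-shaped particle footprint carrying Eu(III)-like lines (580,
592, 612, 618, 650, 698 nm at 2.5–5 nm FWHM, peak 500 counts; the 612/618
doublet lies within the T2 merge distance so the pruning rule is exercised)
and optionally Tb(III)-like lines (545, 585, 620 nm), a sigmoid long-pass
edge at 532 nm rising over 10 channels, on average two cosmic-ray spikes
per cube (1–2 channels, ≥ 50× the local background and at least ten
kilocounts — CCD cosmic events dwarf the photon signal), and Poisson noise
applied last. Line shapes are Gaussian in wavelength; real lanthanide
multiplets are emulated as clusters of Gaussians. Default geometry is
10×10 pixels × 1340 channels, linearly calibrated 500–760 nm.

The defaults are chosen so that the weakest lines (650 nm at 50 counts)
stay below the T1 resolution onset while the rest resolve — the
input-output relationship is deliberately nonlinear at onset and linear
above it, and the tests probe both regimes.

What the phantom does *not* model: read noise and detector QE curves,
instrument spectral response (intensities are uncorrected counts),
photobleaching, sub-pixel particle structure, and spatially varying
background. Passing tests therefore demonstrate the algorithmic
guarantees (zero resolved background off sharp features, anchor placement,
linearity above onset) under idealized but Poisson-noisy conditions; they
do not certify performance on spectra whose *background* itself contains
sharp structure, which violates the core assumption.

## Numerical choices

* Strict inequalities against ±T1, so Δ = ±T1 exactly codes to 0.
* Baseline interpolation is evaluated as S(on) + ((i−on)/(end−on))·(S(end)−S(on))
  on the open interval; endpoints keep B = S exactly, making B continuous
  at anchors by construction.
* T2 pruning compares |1e7/λ_end − 1e7/λ_onset| < T2 and re-scans after
  each merge; the result is order-independent for well-separated bands.
* Early-onset relocation ties are broken toward the channel nearest the
  band maximum.
* Degenerate pixels never abort cube processing; they resolve to zero with
  a recorded warning.
* Smoothing leaves O(1e-14) floating-point dust on constants; tests treat
  anything below 1e-9 counts as zero, while the zero-background guarantee
  of L itself is exact (L is a max(…, 0) of S minus a copy of S).

## Design notes

* The two resolution methods are exposed as sklearn-style transformers
  operating row-wise on (n_spectra, n_channels) matrices, with the
  per-pixel functions (`resolve_method2`, `build_baseline`, …) as the
  underlying API; cube-level helpers wrap them.
* Channel indices are 1-based in every serialized artifact (anchor
  reports, integration windows), matching spectroscopic convention;
  internal arrays are 0-based.
* When no calibration is supplied, a linear 500–760 nm map over the
  channel count is assumed (the working region of a 300 g/mm grating
  centred at 500 nm) — T2 needs wavenumbers, and a documented default
  keeps the tool usable on bare matrices. Override it for real data.
* The constant-threshold comparator X and the region-mean experimental
  background B_exp are included for comparison figures only; neither can
  produce a structured-background-free image.

## Known limitations

* Quantification is slightly biased low: the chord baseline clips the
  sub-T1 tails of each line (≈3% for the default phantom's gated doublet),
  and lines whose gradient never exceeds T1 are not resolved at all. Use a
  single sharp feature, gated, for quantitative work.
* Very broad "narrow" bands (FWHM approaching the 20 nm limit at low
  amplitude) resolve with larger chord losses; the linearity guarantee
  holds only well above the resolution onset.
* A band overlapping the filter edge is recovered via the relocation rule
  with a near-horizontal chord — adequate, but poorer than for free
  standing bands.
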