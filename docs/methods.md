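# Methods

## Scene model

A synthetic field of view contains `n` side-view synapses, each defined by
a center, a unit orientation vector `u` of the scaffold bar's long axis,
and a signed presynaptic side `s ∈ {+1, −1}` along the bar normal
`n = s · R₉₀u`. Three structures are rendered per synapse in nm
coordinates (origin at the top-left pixel center):

- **Scaffold bar** (PSD-95/Gephyrin-like, STED channel): Gaussian
  cross-section along the normal (σ = 30 nm default) times a soft top-hat
  along the axis (length 400 nm default, 20 nm erf roll-off). The
  Gaussian cross-section keeps the normal-direction peak analytic: the
  profile maximum sits exactly at the bar center, which is what makes
  closed-form offset recovery checks possible.
- **Protein band** (protein-of-interest, STED channel): the same bar
  shape displaced by the ground-truth offset `δ` along `+n` (toward the
  presynapse). Knockout-genotype scenes render this band with amplitude
  0, leaving background + noise only.
- **Vesicle cloud** (Synaptophysin-like, confocal channel): a soft disk
  of radius 400 nm whose center sits one radius from the bar along `+n`,
  so the bar lies at the cloud edge. The 400 nm radius gives a
  bouton-scale footprint (≈ 0.5 µm² cross-section), inside the 0.4–2 µm²
  segmentation filter that defines a synaptic punctum.

Each channel is convolved with its own normalized Gaussian PSF — defaults
50 nm FWHM for STED channels and 250 nm for confocal, typical for a
commercial gated-STED instrument and freely configurable — then detector
noise is applied last: counts = gain · Poisson(signal + background/gain)
plus optional Gaussian read noise. Default pixel pitch is 20 nm/px for
STED-scale scenes, which makes the 5-pixel rolling average a 100 nm
window, matching the ±100 nm peak-search window. Per-synapse photon
amplitudes default to 1000 peak photons (scaffold/protein) and 800
(vesicle) over a background of 2 counts — a high-SNR regime in which
detection failures are rare and measurement error is dominated by pixel
quantization. A scene spec plus seed determines every pixel; identical
specs are byte-identical.

Synapses whose bar, band or cloud footprint would leave the image are
rejected with a report rather than clipped silently.

### What the generator does *not* emulate

Real STED images add depletion-dependent PSF tails, fluorophore blinking
and bleaching, antibody linkage error (~10–20 nm), tissue background
structure, out-of-focus light and chromatic offset between channels.
Passing recovery tests therefore demonstrate that the *measurement chain*
is unbiased and correctly implemented under the stated noise model — not
that any specific biological distance estimate is free of labeling or
registration bias.

## Side-view measurement chain

1. **Candidate detection** (automatic mode): both channels are Otsu
   thresholded; scaffold components are kept when elongated (major/minor
   axis ratio ≥ 2), of bar-like length (200–800 nm), adjacent to exactly
   one vesicle cluster (centroid within 200 nm of the cluster boundary)
   and not within 200 nm of another bar. Orientation comes from second
   moments; the profile normal is signed toward the nearest cluster
   centroid. These thresholds are configurable — the selection criteria
   they implement are qualitative ("single bar-like structure at the
   cloud edge"), and manual ROI files (endpoint pairs drawn across the
   bar, post → pre) are supported as the primary alternative.
2. **Profile extraction**: positions −500…+500 nm in one-pixel steps
   along the signed normal; at each position the intensity is the
   bilinear-interpolated mean over the 250 nm width along the bar.
3. **Smoothing**: centered 5-pixel rolling mean; profile ends use
   shrinking windows (mean over available samples) rather than padding,
   so no data are invented at the edges. The window is defined in pixels;
   its nm extent is recorded in output metadata.
4. **Apposition**: scaffold peak = global maximum of the smoothed
   scaffold profile (ties broken toward position 0 and logged); protein
   peak = maximum within ±100 nm inclusive; `window_truncated` is set
   when that maximum sits on a window edge. Distance is signed, +
   toward the presynapse; unsigned summaries are also reported since the
   field usually quotes unsigned distances.
5. **Averaging**: profiles are shifted so their scaffold peaks coincide
   at 0, linearly resampled onto the common one-pixel grid restricted to
   positions covered by every profile, and averaged (mean ± SD/√n).
6. **Positivity**: per culture `g`, threshold `mean(KO_g) + 3·SD(KO_g)`
   (sample SD); strictly-greater comparison; cultures with fewer than two
   KO reference values yield undetermined calls rather than a guess.

## Statistics

Two-sample comparisons are gated: Shapiro on each sample and Levene
across samples (scipy's Brown–Forsythe median-centered variant), all at
α = 0.05; if all pass, an unpaired two-sided t-test, otherwise a
two-sided Mann–Whitney U. Constant samples make Shapiro undefined and
fall back to the rank test with a warning. The profile ANOVA treats
genotype and position (categorical, balanced grid after alignment) as
crossed factors with interaction, fitted by OLS; the genotype main effect
is the headline value. Degenerate inputs (zero residual variance) are
resolved from the raw sums of squares: an absent effect reports F = 0,
p = 1, an effect with no error variance reports an infinite-F flag with
p = 0 and a warning. Significance stars follow the usual *p<0.05,
**p<0.01, ***p<0.001 mapping.

## IPSC metrics

Traces are double exponentials
`I(t) = baseline − A·c·(e^{−(t−t₀)/τ_d} − e^{−(t−t₀)/τ_r})` with `c`
chosen so the extremum magnitude equals `A`; default sampling 0.1 ms
(10 kHz), onset latency 3 ms, and a 2 ms post-stimulus artifact blank
(field-stimulation artifacts are unavoidable; the latency default keeps
the rising phase observable past the blank). Polarity is auto-detected
from the dominant deflection. The peak is refined by parabolic
interpolation through the three samples around the sampled maximum, so
peak time and amplitude are not quantized to the sampling grid; 20/80/33 %
crossing times use linear interpolation between samples. At short
interstimulus intervals the first response's tail is removed before
measuring the second: a single exponential is log-linearly fitted to the
decay from one time-to-peak after the peak up to just before the second
stimulus, extrapolated and subtracted (switchable; without it the ratio
is biased high, and the bias is itself verified against the closed form
in the tests). The second amplitude is measured from the pre-train
baseline.

## Validation experiment sizes

The recovery experiments use 200 synapses per offset on the
{0, 20, 40, 60, 80} nm grid (1 000 single-synapse scenes through the
fully automatic chain), 50 synapses for the N(24, 17²) nm population
recovery, 10⁵ draws for the positivity null calibration, 20 constructed
label images for size-filter exactness, 20 random orientations for the
rotation oracle, 50 random balanced designs for the ANOVA oracle, and
five τ-combinations at 0.01 ms sampling for the kinetics oracle (fine
sampling isolates algorithmic error from sampling quantization). These
sizes give stable statistics while keeping the whole validation run
around ten seconds on one CPU.

## Known limitations

- The offset estimator is quantized to the pixel grid (no sub-pixel peak
  interpolation on image profiles); at 20 nm pixels the worst-case
  per-synapse error is half a pixel, and population SDs are mildly
  shrunk by quantization and by the ±100 nm window clipping extreme
  offsets.
- The automatic side-view detector is tuned for isolated synapses; it
  deliberately rejects ambiguous configurations (two adjacent clouds,
  touching bars) rather than guessing, so dense fields yield fewer, not
  worse, measurements.
- Density is normalized per 100 µm² of imaged field (flagged in the
  output metadata), not per dendrite length.
- No multiple-testing correction across markers and no mixed-effects
  modeling of culture as a random factor; culture enters only through
  the per-culture positivity thresholds.
- 2D only; no z-stacks, no depletion-physics STED PSFs, no photophysics.
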