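# Methods

This note records the measurement models implemented in phantomiq, the
defaults chosen where common QA practice leaves a choice open, and what the
synthetic phantom does and does not emulate.

## Synthetic phantom

A phantom slice is a constant background (default 0 HU, i.e.
water-equivalent) carrying disk inserts, optionally inside a circular body
(default radius 150 mm) surrounded by air at −1000 HU. The default grid is
1024 px over a 400-mm field of view (0.390625 mm/px, slice thickness
0.5 mm); smaller grids with the same pixel spacing are used throughout the
tests to keep runtimes low without changing any geometry-dependent result.

**Sharp rendering (blur σ = 0).** Each pixel's value is
`background + contrast × (fraction of the pixel area inside the disk)`.
Interior/exterior pixels are classified by centre distance; for boundary
pixels the covered fraction is the exact chord overlap in y integrated over
x with 256-point midpoint quadrature. The integrated excess HU·area of a
rendered disk matches the analytic `contrast × πr²` to ~10⁻⁵ relative even
for a 2-mm disk, which is what the downstream edge analysis requires.

**Blurred rendering (σ > 0).** The scene is convolved with an isotropic
Gaussian *in the continuous domain* rather than with a discrete kernel. A
disk of radius R convolved with N(0, σ²I₂), evaluated at distance d from
its centre, is the noncentral-χ² probability
`P(χ'²₂((d/σ)²) ≤ (R/σ)²)` (a Marcum-Q expression), which is evaluated
directly at pixel centres. Two consequences matter:

* the true MTF of the rendered scene is exactly `exp(−2π²σ²f²)` — there is
  no pixel-aperture or kernel-sampling term — so resolution recovery can be
  tested against a closed form;
* frequencies above the grid Nyquist (1.28 cycles/mm) remain physically
  meaningful: a discrete convolution kernel is periodic in frequency and
  cannot realize Gaussian attenuation there at all, which is why a 0.2-mm
  blur (true f10 ≈ 1.71 cycles/mm) is only recoverable under this
  rendering. The oversampled radial ESF (below) samples far above the grid
  Nyquist and can measure it.

**Noise** is added after blurring — it models reconstruction noise, not
scene noise — independently per slice, as white Gaussian noise, white noise
shaped by a Gaussian low-pass transfer `exp(−2π²ℓ²f²)` (correlation length
ℓ in mm), or white noise filtered by the square root of an arbitrary target
NPS curve. Filters are normalized to unit mean-square gain so the per-pixel
SD equals `sigma_hu` in expectation. Identical (spec, seed) pairs give
bit-identical stacks (a single PCG64 stream consumed slice by slice).

**Presets.** The sensitometry module places 12-mm disks of 340, 120 and
−35 HU at the 9, 11 and 1 o'clock positions (50-mm ring) plus a 990-HU
disk at 5 o'clock as the resolution target; the uniformity module has no
inserts; the low-contrast module places disks of 15, 9, 8, 7, 6, 5, 4, 3
and 2 mm at the 1.0% contrast level. The HU meaning of "1.0% contrast" is
a parameter (`hu_per_percent`, default 10 HU — the common 1000-HU reference
convention), since the physical phantom's datasheet convention is not
restated by most protocols.

**Not emulated:** projection/sinogram physics, reconstruction algorithms,
the oval body annulus (body size enters only through the user-chosen noise
parameters), beam hardening, and spatially varying noise. Consequently,
passing tests demonstrate that the *measurement chain* is correct, not that
any scanner or reconstruction behaves in a particular way.

## Line-ROI measurements

Profiles are sampled at `length_pixels` points spaced exactly one pixel
apart along a line through the insert centre, rotated in 1° steps over
360°, on every slice. Interpolation is bilinear by default and configurable
to nearest-neighbour. The CT number is the grand mean ± grand SD over all
samples (the SD of per-angle means is also reported); pooling was chosen
because the per-sample dispersion is the quantity comparable to the image
noise level. Note that bilinear interpolation at generic sub-pixel
positions attenuates white noise — the grand SD under bilinear sampling
reads ≈0.66 of the true pixel SD, which is a property of the interpolator,
not an error; nearest-neighbour sampling recovers the unattenuated SD and
is what SD-recovery tests use.

The default lengths are 27 pixels (≈ ±5.1 mm, safely inside a 12-mm
insert) for CT numbers and 51 pixels (≈ ±10 mm, bracketing the insert and
background) for attenuation profile curves. A Gaussian-blurred disk's mean
profile crosses half amplitude at the true edge radius up to a curvature
term `½·e^(−a²)·I₀(a²)` with `a = R/σ` (≈1.7% of contrast at R = 6 mm,
σ = 0.5 mm), which bounds how precisely the APC can localize the edge.

## Noise magnitude and NPS

Noise is the per-slice SD of a centred 256 × 256-pixel ROI, averaged over
the slices (mean, with the SE of per-slice SDs); a single slice reports its
SD with the SE marked unavailable rather than zero. Dose ratios are
`round_half_up(100 × test/reference)` — half-up reproduces the conventional
integer percentages from one-decimal HU inputs.

The NPS estimator detrends each ROI (mean subtraction by default; an
optional first-order plane fit guards against synthetic shading), computes
`|FFT2|² · Δx²/N²` per slice, averages across slices, and bins by the
Euclidean norm of the frequency coordinates with bin width `1/(N·Δx)` (the
DFT spacing — no interpolation at low frequency). The DC sample is
excluded; empty bins are dropped; the axis runs to the corner frequency
(√2 × Nyquist) so that binning conserves total power exactly. No window is
applied: the periodogram of a stationary noise field needs none, and
Parseval (2-D integral = detrended ROI variance) then holds to machine
precision. The normalized NPS divides by the trapezoidal area under the
radial curve and integrates to 1 by construction.

Statistical accuracy per radial bin is set by its 2-D ring occupancy: the
innermost bins hold only ~8 conjugate-paired DFT samples per slice, so even
50 slices leave ~7% relative scatter there. Estimator-accuracy checks are
therefore stated over bins with ring occupancy ≥ 100 samples per
realization (radial index ≳ 16), where the 50-slice bin-mean scatter is
below 2%; the sparse low-frequency bins are still reported, with their
occupancy, for the user to judge. Sub-ROI averaging is available as an
option when more low-frequency averaging is wanted.

## Circular-edge MTF

Chain: pixel-wise signal average over the stack → disk centre refined by an
intensity-weighted centroid (background from the surrounding annulus) →
every pixel within ±3 mm of the nominal edge radius binned by its exact
radial distance at 0.1-pixel pitch → ESF → central-difference LSF → DFT
magnitude normalized at zero frequency → f50/f10 by linear interpolation at
the first downward crossing.

Numerical choices, each of which was validated against the Gaussian closed
form `f_p = √(ln(1/p)/(2π²σ²))`:

* **Bin positioning.** Each occupied bin's mean value is placed at its
  samples' mean radius (not the bin centre) before resampling onto the
  uniform grid; with sparse bins on small grids, centre-of-bin placement
  leaves sub-bin position jitter that biases f50/f10 by several percent.
  Empty bins are filled by the same linear interpolation.
* **Radius refinement.** The nominal radius is refined once from the
  half-amplitude crossing of a provisional ESF (the half-amplitude point of
  a symmetrically blurred edge is the true edge), removing dependence on
  the user's nominal value.
* **Windowing.** The LSF is baseline-corrected (mean of the outer 10% tails
  subtracted) and tapered with a Tukey window acting on the outer 25% of
  the record. A full Hann taper, common in slanted-edge codes, narrows a
  wide LSF (σ = 0.5 mm spans a ±6σ record here) and biases f50/f10 upward
  by up to +7%; the flat-topped Tukey taper keeps the bias below 0.5% while
  still suppressing truncation leakage from noisy tails.
* **Readout.** First downward crossing with linear interpolation — robust
  to high-frequency noise lobes. The record is zero-padded 8× so the
  crossing interpolation error is negligible.

Recovered f50/f10 match the closed form within 1.5% noiseless and within
~1.5% at 15-HU noise with 50-slice averaging, for σ ∈ {0.2, 0.3, 0.5} mm
(residual bias is dominated by the central-difference derivative's
`sinc`-like transfer, <0.7%). Replicate stacks (the package's stand-in for
re-reconstructing the scene at shifted slice positions, which has no
software equivalent) give the across-replicate SE of f50 and f10.

The curvature of the circular edge enters the LSF as a √(r/R) tilt; its
effect on the readouts is O((πσ²f/R)²) ≈ 0.1% at R = 6 mm and is ignored.

## Detectability surrogate and kappa

Human low-contrast readings are not reproducible by software. The surrogate
is a non-prewhitening matched filter for a disk template: under white noise
`SNR = (C/σ)·√(πd²/4)/Δx`, with an NPS-weighted variant
`SNR² = (∫S²)²/∫S²W` (disk spectrum `S ∝ 2J₁(x)/x`) for textured noise.
Detection is declared at a Rose-type threshold (default 5), and the minimum
detectable diameter is the smallest ladder entry meeting it. The surrogate
is monotone in contrast, diameter and inverse noise; its absolute values
are not calibrated to human observers and are not comparable to published
reader studies.

Cohen's kappa is unweighted, computed from the raters' cross-tabulation
(`κ = (p_o − p_e)/(1 − p_e)`), with bands poor/<0.01, slight ≤0.20, fair
≤0.40, moderate ≤0.60, substantial ≤0.80, almost perfect ≤1.0. When both
raters are constant on the same category, κ is 0/0 and is reported as
undefined rather than 0 or 1. Weighted kappa is intentionally not offered
as the default because the interpretation bands above are conventionally
attached to the unweighted statistic.

## Pipeline and problem sizes

`run_protocol` evaluates each condition independently (an error in one
condition is recorded and does not abort the others), derives per-condition
noise seeds deterministically from the protocol seed, and writes every
table as CSV plus a provenance block listing all of the defaults above. The
bundled tests and the acceptance script run the measurements on grids of
128–1024 px (always at 0.390625 mm/px) with 50-slice stacks — the package's
standard problem sizes, chosen so that every estimator operates in the same
sampling regime as the full-size phantom.

## Known limitations

* The phantom is piecewise-constant disks plus stationary additive noise;
  nonstationary noise, streaks, and reconstruction nonlinearity (the
  interesting failure modes of iterative/learned reconstructions) are out
  of scope, so conclusions about such algorithms cannot be drawn from the
  synthetic stacks themselves.
* DICOM output quantizes HU to integers (slope 1 / intercept −1024);
  bit-exact round trips use the raw `.npy` + YAML format.
* The NPW surrogate ignores observer internal noise and eye filters; a
  channelized-Hotelling observer would be the natural extension.
* The ESF assumes a rotationally symmetric point-spread function; an
  anisotropic blur would be averaged over angle by the radial binning.
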