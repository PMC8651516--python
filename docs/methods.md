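# Methods

This note records the models behind `gpfcs`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Membrane-diffusion photon simulation (`simkit`)

**Model.** Dye molecules perform independent 2D Brownian motion
(supported-bilayer geometry; no vesicle curvature, no axial structure) in
a square patch of side `box_side` (default 10 × ω₀ = 2.9 µm). A fixed
Gaussian observation spot at the patch center excites each molecule with
profile exp(−2r²/ω₀²); detected photons per bin are Poisson with the
summed molecular rate, and each photon falls in the blue channel with
probability (1 + GP)/2 — so the simulated GP is exact by construction.

**Open (grand-canonical) boundaries.** The patch is open: a molecule
stepping outside is handed back to a surrounding uniform bath, and
entrants arrive as a Poisson boundary flux with the overshoot-depth
distribution of a uniform bath (expected flux 4·L·c·√(DΔt/π) per step).
For independent molecules this reproduces an unbounded membrane exactly,
up to the detector's sensitivity at the boundary (exp(−50) of peak). The
in-patch molecule number is then Poisson at every instant. This matters:
a *closed* patch with a conserved number M imprints a constant −1/M
offset on the normalized autocorrelation — at M ≈ 320 this biased fitted
anomaly exponents by +0.09 — because the per-trace normalization cannot
average over number fluctuations that never happen. The open boundary
removes the artifact at its source rather than patching the fitter.

**Time stepping.** Positions advance on the coarsest grid that keeps the
RMS step below ω₀/10 (Δt_pos = (ω₀/10)²/(4D), rounded down to a whole
number of photon bins); the emission rate is held constant between
updates. At ω₀/10 the within-step intensity change is ≲1%, far below
shot noise, while stepping every 1-µs bin would cost ~10¹⁰ RNG draws per
10-s trace for no measurable accuracy gain. If the photon bin itself
violates the displacement bound, `simulate_trace` raises and names
`bin_width` as the limiting parameter. Step increments are generated in
bulk as float32 (step ≈ ω₀/14; single-precision rounding is orders of
magnitude below thermal motion) and consumed by a compiled bookkeeping
loop.

**Exchange and bleaching.** Exchangeable dyes unbind with constant
hazard `k_off` and are instantly replaced by fresh dye at a uniform
position — only the stationarity of the bound pool matters for the
analyses, so solution-phase diffusion is not simulated. Bleaching is a
one-step process with hazard `bleach_rate`·exp(−2r²/ω₀²); a bleached
permanent dye stays dark, a bleached exchangeable dye is replaced on its
next unbinding. The exponential-dwell assumption is exactly that — an
assumption; measured dwell-time distributions of exchangeable probes are
not published beyond their ~ms scale. These paths run a per-step
event loop (vectorized over molecules) and are used with shorter traces.

**Defaults** mirror the acquisition they emulate: 1-µs bins, 10-s
traces, ω₀ = 290 nm confocal reference, 32 spectral channels of 8.9 nm
starting at 570 nm, analysis wavelengths 575/640 nm, brightness 25 kHz
peak per molecule (CPM ≈ 12.5 kHz, mid-range for bright membrane
probes).

**Spectral images.** Each lipid phase is a single Gaussian emission
spectrum (width σ_λ, default 30 nm — full line shapes are not published,
so σ_λ is a free parameter); expected channel counts integrate that
Gaussian over each 8.9-nm window. A phase may be specified by its
emission peak or by a target GP, inverted through the channel-integral
GP (unique because GP is monotone in the peak wavelength). The analytic
channel-integral GP of each sector is the oracle all GP-recovery tests
compare against; the vesicle ring has a Gaussian radial profile and
Poisson noise throughout.

**Time-lapses** render a concentric cell scene (membrane ring, cytosol,
nucleus, empty background) in two emission bands. Permanent dye decays
geometrically per frame (optionally with different blue/red rates, which
reproduces the apparent GP drift of a bleaching permanent probe);
exchangeable dye is stationary with an optional linear cytosol rise
(internalization). Poisson noise per pixel.

**What passing tests do not show.** The generators contain no triplet or
dark-state photophysics, no STED depletion physics, no anomalous-
diffusion ground truth (α ≠ 1 is fitted but never generated), no optical
aberrations, drift, or detector afterpulsing. Agreement on this
synthetic data validates the estimators' correctness, not their
robustness to every artifact of real recordings.

## Correlation (`correlate`)

Multiple-tau scheme, m = 16 points per octave: the first 2m lags at
native bin width, then the trace is rebinned by two per octave and lags
m+1…2m evaluated at each level. Normalization is symmetric — leading and
lagged segments are normalized by their own means — which suppresses the
O(τ/T) bias of the single-mean estimator. The zero-lag (shot-noise)
point is never reported. `brute_force_acf` evaluates the identical
estimator directly at integer-bin lags and serves as the independent
oracle: first-octave values agree to 10⁻¹⁰ relative.

## Diffusion fitting (`fcsfit`)

Unweighted least squares of G(τ) = (1/N)(1 + (τ/τ_D)^α)⁻¹ (lmfit),
initialized from the curve itself (N₀ = 1/g(first lag), τ_D,₀ at the
half-decay lag, α₀ = 1), α bounded to [0.5, 2]. No triplet term and no
baseline by default — an additive offset exists behind a flag for
real-data robustness. Degenerate curves (monotonically increasing, all
non-positive) return `converged=False` with a diagnostic instead of
raising.

**Fit window.** `analyze_trace` fits twice: a full-range pass locates
τ_D, then the reported fit uses lags ≤ 2·τ̂_D (never less than two
decades of lag). The long-lag tail of a single-trace ACF carries noise
that is strongly correlated across lags (slow occupancy fluctuations;
measured per-lag SD is roughly flat at ~0.002–0.003 for a 10-s trace
while the model there is smaller than that), and an unweighted fit that
includes hundreds of such points roughly doubles the variance of α. The
window multiplier was calibrated once on simulated ground truth
(α SD 0.030 at 2·τ_D vs 0.055 at 25·τ_D, with τ_D and N unbiased);
diagonal inverse-variance weighting does not help because the noise
correlation, not the per-point variance, is the problem. Single-trace α
estimates at these acquisition settings still carry an irreducible
SD ≈ 0.03 — replicate α values spanning roughly 0.96–1.08 on truly
Brownian data are expected behavior, which is why condition-level
statements about α should be made on replicate averages.

## Calibration (`calibrate`)

ω₀(STED) = ω₀,conf · √(τ_D,STED/τ_D,conf) with ω₀,conf = 290 nm by
default (instrument-specific, configurable); D = ω₀²/(4τ_D) with
centralized nm/ms/µm² conversions. STED powers are opaque labels — no
power-to-resolution curve is modeled. Note that D computed from the
*apparent* radius is algebraically identical for every entry (it equals
the confocal D), so the meaningful invariance check — performed in the
tests — recovers D from each spot's true radius and its own fitted τ_D.

## GP imaging (`gpimage`)

Nearest-channel selection (no interpolation) for Ib/Ir: it matches the
discrete detector and is exactly testable. Spectral path: absolute
intensity threshold on the channel-summed image, default 40 counts;
two-band path: fractional threshold, default 0.25 of the maximal channel
sum (the 20–30% range customary for such images). The Fiji GP plugin's
"noise tolerance" parameter has no published semantics and is not
imitated; reproducible thresholds were preferred over plugin mimicry.
Mean spectra are per-channel means over a mask — no line-shape fitting.
Experiment-level GP is the mean of per-image means (images weighted
equally). Pixels with Ib + Ir = 0 are always masked; a threshold that
masks everything yields a flagged empty result, not an exception.

## Time-lapse quantification (`quant`)

ROI masks are caller-supplied (TIFF masks or rectangles) — phase and
compartment selection is manual in practice and no segmentation is
attempted. Bleach curves subtract a signal-free background region per
frame and normalize to frame 1; adding any constant offset to all pixels
cancels exactly. Internalization reports each compartment as percent of
the same frame's membrane mean. GP time-courses threshold within the ROI
per frame; frames whose ROI empties (vesicle out of plane) yield NaN and
the series continues.

## Problem sizes used in tests and the acceptance script

Replicate α studies: 20 traces × 10 s at 1-µs bins, ~10 molecules per
spot. Parameter-recovery grid: occupancies {2, 10, 50} × transit times
{0.5, 2, 10} ms, one 10-s trace per cell. Spot-size invariance: radii
{290, 150, 80} nm at D = 2 µm²/s. Vesicle stacks: 64×64 px × 32
channels. These sizes keep a full run within minutes on one CPU while
leaving every statistical tolerance dominated by the physics, not the
budget.

## Known limitations

- The fitter supports α ≠ 1 but the simulator never generates it; α
  recovery below/above 1 is validated only on noiseless synthetic
  curves.
- No cross-correlation between spectral channels, no lifetime/gating.
- The open-boundary bath assumes ideal (non-interacting) molecules;
  crowding or binding-site saturation would invalidate the Poisson
  injection statistics.
- Acquisition-side procedures (refocusing between measurements, STED
  beam alignment) have no computational analog and are out of scope.
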