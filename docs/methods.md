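# Methods

This note documents the models behind `ip3rkit`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not establish about real recordings.

## Chelator equilibria (`buffers`)

A single-metal multi-chelator solution at equilibrium obeys

    Ca_total = Ca_free + Σᵢ Tᵢ·Ca_free/(Ca_free + Kdᵢ),

where `Tᵢ` is chelator *i*'s total concentration and `Kdᵢ` its apparent
Ca²⁺ dissociation constant. The forward map (free from total) is solved
by bracketed root finding on `[0, Ca_total]` — the conservation function
is strictly monotone, so the root is unique; the solver runs at relative
tolerance 1e−12 with an absolute floor of 1e−30 M so that heavily
buffered solutions (free Ca²⁺ ≪ 1 pM) still resolve. The inverse is the
closed form `total = free·(1 + Σᵢ Tᵢ/(free + Kdᵢ))`.

Apparent Kd values depend on pH, temperature and ionic strength. The
shipped table (EGTA 150 nM, BAPTA 220 nM, dibromo-BAPTA 1.6 µM; pH 7.4,
~22 °C, ~0.1 M ionic strength) is frozen for reproducibility and
overridable per `ChelatorSpec`. Mg²⁺/ATP competition and protonation
equilibria are out of scope: the package treats Ca²⁺-only apparent
constants.

## Gating models (`gating`)

*Hill activation* `Po = Pmax/(1+(EC50/L)^h)` and the *biphasic* product
of activation and inhibition Hill terms carry the ligand dependence of
open probability. `Pmax` values are modelling choices (WT 0.1; D2594K
3.6× WT for IP₃ activation, ~3× for the Ca²⁺ bell), because published
dose–response figures report midpoints and slopes, not absolute
ceilings; all midpoint-recovery analyses are invariant to `Pmax`
scaling.

*Joint surface.* Per-axis experiments fix the co-ligands, so no joint
equation is implied by them. The simulator's `LigandSurface` composes
`Po(IP₃, Ca) = Pmax · f_IP₃ · f_Ca` with each factor normalized to a
unit ceiling (the biphasic factor by its grid-searched peak). Per-axis
fits never depend on this composition rule.

*Nernst/driving force.* `E_Ca = (RT/zF)·ln([Ca]cis/[Ca]trans)` with
R = 8.314 J/(K·mol), F = 96485 C/mol, z = 2, T = 295.15 K by default;
`EDF = Em − E_Ca`, with the trans (luminal) side carrying the applied
potential and positive EDF driving lumen-to-cytosol flux.

*Feedthrough MOT model.* Normalized mean open time versus EDF follows
`1 + Range·[1+(Va50/EDF)^Ha]⁻¹·[1+(EDF/Vi50)^Hi]⁻¹`. For EDF ≤ 0 the
model is pinned to the baseline value 1: with no lumen-to-cytosol flux
there is no feedthrough, the flat luminal dependence observed at
negative potentials supports a constant, and the expression itself is
undefined for negative bases with non-integer exponents. `Range` is not
separately published; the default 3.0 sets the curve's peak near 2.7×
baseline, and Va₅₀/Vi₅₀ recovery is insensitive to it.

*Two-state rates.* `rates_from_po` maps an equilibrium target (Po, MOT)
onto closing = 1/MOT and opening = Po/((1−Po)·MOT), so the implied
equilibrium open fraction is exactly Po. The simulator uses MOT = 8 ms,
a typical single-IP₃R mean open time at activating ligand levels.

## Bilayer simulator (`bilayersim`)

Gating is a two-state Markov process with exponential dwells, started
from equilibrium, simulated per channel (channels gate independently and
identically — the assumption implicit in treating nPo as n·Po). Open
counts are rendered at 20 kHz, multiplied by the unitary current
γ·(Em−Erev)/1000 (248 pS at +30 mV → 7.44 pA), low-pass filtered with a
Gaussian FIR whose −3 dB point sits at the 2 kHz corner
(σ = √(ln 2)/(2π·fc); the sampled kernel lands within ~0.5 dB of the
continuous target), and summed with white Gaussian noise. The default
pre-filter noise SD of 0.8 pA leaves ~0.37 pA after filtering, placing
the half-amplitude threshold ~10 noise SDs above baseline, so false
events are negligible at the default operating point; the value is
configurable for robustness studies. Flicker noise, drift and capacitive
transients are not modelled.

## Idealization and statistics (`idealize`)

Half-amplitude idealization assigns each sample the conductance level
whose half-amplitude window contains it; runs of equal level become
events. Durations are stored as integer sample counts, which makes total
duration conservation through censoring exact. Dead-time censoring
(default 300 µs, i.e. events strictly shorter are removed) merges each
censored event into its flanks — equal-level flanks concatenate,
otherwise the longer flank absorbs it (ties to the preceding event) —
and is idempotent. A single threshold per level is used (no dual-
threshold hysteresis); noise chatter is handled by the dead time.

`channel_stats` reports nPo = Σk·t_k/T; MOT/MCT are arithmetic dwell
means, reported only for effective single-channel records (max level 1).
For stacked records the per-channel open time is not identifiable from
level dwells, mirroring the practice of restricting kinetic analysis to
single-channel recordings; `mot_applicable=False` flags this. An
exponential-mixture ML fit (EM, 1 vs 2 components by likelihood ratio at
α = 0.05) is available for dwell-time diagnostics; the arithmetic mean is
the primary estimator. Records under 3 minutes warn rather than fail.
Baseline auto-detection uses the amplitude-histogram mode (robust at low
Po); the channel count is the maximum observed stacking level,
corroborated by the smoothed all-points histogram's mode count.

## Curve fitting (`fits`)

Nonlinear fits run on linear concentration with log-parameterized
midpoints (positivity) and a fixed multi-start grid: midpoint seeds
log-spaced over the data's x-range, Hill slopes {1, 2, 4}; the best-RSS
solution wins, ties to the smaller slope. The biphasic fit enforces
IC₅₀ > EC₅₀ by the ordered parameterization `ln IC50 = ln EC50 + e^g`.
Weights are 1/y_err² when errors are supplied — and should be: with
multiplicative noise, unweighted least squares effectively ignores the
low-Po limbs that identify the midpoints (in a 40-replicate calibration
at 3 % noise the weighted biphasic fit's median midpoint error is 2.5 %
versus 8 % unweighted). Standard errors come from the Jacobian at the
solution; degenerate data (flat response, missing descending limb)
produce flagged results, not exceptions. The MOT-EDF fit fixes the
baseline at 1 and bounds midpoints to [10, 500] mV and exponents to
[0.5, 20]. The MCT overlay fits `a − b·MOT_model(EDF)` linearly with
b ≥ 0 and compares against a constant-only fit by F-test.
`dose_response_pipeline` composes idealization, censoring and nPo
pooling over conditions, then the requested fit; normalized responses
divide by the first/lowest-|EDF| condition, recorded in provenance.

## Linescan generator and puff detector (`puffs`)

Each synthetic puff is a linear rise (duration r) to peak followed by a
single-exponential decay (τ), times a Gaussian spatial profile (σ = 1 µm
default), on a baseline of 100 a.u. with white Gaussian noise. This
minimal form reproduces the four standard kinetic read-outs in closed
form: rise₂₀₋₈₀ = 0.6r, time-to-peak = r, decay₈₀₋₂₀ = τ·ln 4, FDHM =
0.5r + τ·ln 2. Registry values set (r, τ) through these identities so
WT events carry the published 20–80 % rise (0.35 s) and FDHM (0.68 s),
and mutant events 0.76 s and 2.39 s. A single (r, τ) pair cannot also
match the published 80–20 % decay exactly (real puffs are not single-
exponential); FDHM and rise were prioritized. Cells are 10 µm blocks
separated by 2.5 µm of event-free background, with homogeneous-Poisson
event times and uniform positions per cell; event amplitude defaults to
2 ΔF/F₀ against a 0.2 ΔF/F₀ noise floor (10 background SDs).

ΔF/F₀ uses a per-pixel baseline: the 25th percentile of the pixel's time
course plus a Gaussian truncation correction (0.6745·σ̂, σ̂ from temporal
first differences). The low quantile is insensitive to sparse events;
the correction removes the bias the quantile inherits from the noise
itself (an uncorrected lowest-quartile mean under-reads F₀ by 1.27σ and
inflates every ΔF/F₀ value by tens of percent at realistic noise).

Detection thresholds a lightly smoothed copy of the ΔF/F₀ image
(Gaussian, 1 px/1 line) at `median + k·SD`, k = 5.5 by default within
the conventional 5–6.5 band. The background SD comes from temporal first
differences scaled by the smoothing kernel's L2 norm — the whole-image
MAD is inflated by event signal once activity is dense. Touching events
are separated by watershed segmentation seeded at h-maxima (peaks
standing ≥ 4 noise SDs above their saddle, so noise cannot seed a
split); mask regions without a marker (threshold flicker of decaying
tails) are discarded. A second, subtract-and-rescan pass fits and
removes every detected event (matched-filter amplitude on the raw image;
Gaussian spatial profile from deconvolved second moments) and re-detects
on the residual, recovering events masked by an overlapping neighbour; a
recovered event must carry a fully significant raw amplitude (≥ k·σ_raw)
so that structured subtraction residuals are not admitted.

Kinetic read-outs are threshold crossings located by linear
interpolation. On noisy traces, first-passage crossings are biased early
wherever the slope is shallow relative to the noise, so the detector
fits the event model (amplitude, start, r, τ, plus a constant local
baseline) to the raw peak-pixel time course over a generous window and
measures the crossings on the fitted curve, evaluated on a 10× finer
grid than the line period (sampling the peak at the line period alone
biases FDHM ~+6 % for fast events). All durations are floored at one
line period; events whose decay outruns the record are right-censored.
`measure_kinetics` itself remains a pure crossing read-out and satisfies
the closed-form identities to within one sample on clean profiles.

What the benchmarks show — and don't. Detector recall and precision are
≥ 0.95 / ≈ 0.99 on images whose events match the generator's shape; the
model-based denoising step shares that shape with the generator, so
real-data kinetics (non-exponential decays, dye saturation, motion)
will be measured less precisely than these figures suggest, and the raw
crossing fallback then applies. At the mutant event density
(0.1 events/s/cell, FDHM 2.39 s) ~6–9 % of events overlap a neighbour too
closely (same cell, |Δt| ≲ 1 s, |Δx| ≲ 2σ) for any threshold detector to
resolve, so detected per-cell frequency under-reads the generating rate
by about that margin; kinetic averages exclude overlap-split and
censored events for this reason. Kinetic benchmarks therefore generate
at sparse density (0.02 events/s/cell over as many cells as needed for
≥ 60 events) — the genotype enters through the event kinetics, which is
the quantity under test.

## Plate assay (`plateassay`)

Well traces follow `F(t) = F₀·[1 + A·(1−e^(−t/rise_τ))·e^(−t/decay_τ)]`
after the stimulus at t = 0, with a 20 s pre-stimulus baseline, default
rise_τ = 5 s and decay_τ = 30 s (peak at `a·ln(1+b/a)` ≈ 9.7 s, peak
factor ≈ 0.62), sampling every 2 s, and additive noise (5 % of F₀ in the
benchmarks). The driving amplitude A follows a Hill curve of ATP whose
ceiling (3 ΔF/F₀ WT, 6 mutant) and slope (1.5) are generator choices;
EC₅₀ recovery is invariant to both. `max_dff` is the maximum of
(F−F₀)/F₀ against the pre-stimulus mean and is scale-invariant.
Extracellular 0-Ca²⁺ conditions are represented by the absence of any
influx component; store depletion and dye saturation are not modelled.

## Benchmark problem sizes

The recovery benchmarks (`ip3rkit.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: 8 ATP
levels × 6 wells at 5 % noise; 6 voltages × 6 replicate amplitudes at
0.2 pA noise (matching the pooled n per point of single-channel i–V
data); 7 IP₃ levels × 3 one-minute single-channel records (a scaled-down
stand-in for >3-minute experimental records; the Hill fit pools nPo
across records); 12 Ca²⁺ levels at 3 % noise for the biphasic fit; 12
EDF points at 5 % noise for the feedthrough refit; linescans with ≥ 60
events for kinetics and 64 cells × 120 s for frequency. Every random
draw descends from the caller's integer seed through
`numpy.random.SeedSequence`.
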