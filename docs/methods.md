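# Methods

This note documents the models, defaults and design choices behind
`cplearn`, in the spirit of a methods section: what each component assumes,
which knobs matter, and what the synthetic-data results do and do not show.

## Stimuli

A stimulus is the luminance field
`L(x,y) = (1 + c_p/100·G(x,y) + c_n/100·N(x,y))·L0` on a 300×300 grid
spanning 5.3°×5.3° of visual angle (background `L0` = 51.9 cd/m²; noise
contrast `c_n` fixed at 15%). The Gabor term is
`G = exp(−(x²+y²)/2σ²)·sin(2πf(x cosθ + y sinθ) + φ)` with f = 1.25
cycles/°, σ = 0.6°, θ = ±20° around the 0° (vertical) or 90° (horizontal)
reference axis, and carrier phase given in cycles (ψ = 0.25, applied as
φ = 2πψ = π/2, so G(0,0) = 1). Values with |G| < 0.005 are zeroed; note the
envelope-only closed form for that cut, σ√(2 ln 200) ≈ 1.95°, is the radius
the trim rule actually produces on our grid.

The noise field uses a band-pass power spectrum built as the difference of
two radial order-3 Butterworth low-pass profiles with cutoffs one octave
below and above the carrier (0.625 and 2.5 cycles/°), uniform random phases,
and the real part of the inverse FFT. Two conventions the construction does
not pin down are made explicit and configurable:

* **Amplitude.** The difference profile is treated as a *power* spectrum
  (amplitude = its square root). Order-3 shoulders mean roughly 30% of the
  realized power sits outside the strict octave band; within a half-octave
  margin the leakage is under 10%.
* **Normalization.** After synthesis the field is standardized to unit peak
  absolute value, so `c_n` acts as a peak contrast exactly like `c_p`
  (`noise_peak_normalized=True` by default).

The circular aperture multiplies deviations from `L0` by the radial window
`W(r) = 1/(1 + (2·0.275·r)^14)` — unity at the center, half-amplitude at
1.82°, effectively zero at the 2.5° crop radius where the image is hard-set
to background. Coordinates put (0,0) at the image center with pixel centers
on half-integer offsets; negative luminances (possible only for extreme
mixtures) clip to zero with a warning.

## Orientation energy

The front end is a quadrature-energy filter bank: per (orientation,
frequency) channel a cosine/sine Gabor kernel pair (DC-removed), responses
squared and summed into a phase-invariant energy map, pooled over space.
Defaults: channels at −20°, 20°, 70°, 110° × 1.25 cycles/°, 1-octave
half-amplitude bandwidth (envelope SD from the standard Gabor bandwidth
relation), kernel extent 6 envelope SDs, and **sum** pooling. Pooling and
bandwidth are configuration, since any location-tolerant energy readout
consistent with an images-in/energies-out contract is admissible; sum
pooling makes energy exactly quadratic in contrast, which the tests exploit.
Images are contrast-normalized internally ((L−L0)/L0) before filtering.

For model fitting, energies are normalized by the session maximum (the
largest raw energy over the stream becomes 1). For generative simulation a
session maximum would be acausal, so raw energies are divided by a fixed
constant calibrated once from a 200-stimulus burn-in at the 8% reference
contrast.

## Learning model

State: four readout weights plus the expected confidence `c̄` (initialized
at mid-scale 0.5 and carried continuously across runs; both choices are
flags). Per trial, in order: activities → `DV = A_cw − A_ccw` → choice
(softmax in `β·DV`) and certainty `c′ = λ|DV|` → confidence (generative:
Gaussian around `c′` with SD `σ_c`, clipped to [0,1]; conditioned: the
observed report) → prediction error `δ = c − c̄` against the *pre-update*
`c̄` → weight update into the chosen unit only
(`Δw_i,choice = α_w·δ·E_i·A_choice`) → `c̄` update. In conditioned mode the
observed choice and confidence drive learning, and the joint log likelihood
accumulates the softmax choice term and the censored-Gaussian confidence
term (interior reports: Normal density; reports exactly at 0/1: tail mass,
so the report distribution integrates to one).

A dynamical property worth knowing: because only the chosen unit's incoming
weights update and the update is proportional to that unit's activity, large
learning rates (α_w ≳ 0.02 at our default scales) enter a rich-get-richer
runaway — one unit's weights inflate, choices develop a bias, certainty
saturates the confidence scale and accuracy collapses toward chance. The
defaults sit far below this regime; simulation studies that crank α_w should
watch for it.

## Staircases

Phase 1 is one-up-one-down with multiplicative 10^±0.05 steps from 20%
contrast; after 3 reversals it hands over to the weighted one-up-two-down
phase (down 0.33 contrast points after two consecutive correct responses,
up 0.33/0.5488 after any error), terminating at the 9th reversal overall
(coarse reversals included; a reset-at-switch flag is provided). A reversal
is any change in the direction of contrast adjustment, recorded at the
pre-step contrast; direction memory persists across no-move trials (the
first correct response of a pair), the standard convention. The equilibrium
of the weighted phase solves `p^n·down = (1−p^n)·up`; for ratio 0.5488 and
n = 2, p = 0.80353. Test sessions interleave independent staircases per
reference axis in 16-trial blocks; the threshold estimate is the mean of
weighted-phase reversal contrasts — a field-standard estimator the protocol
itself does not fix. Single-session estimates carry an SD of roughly 2–3
contrast points under these termination rules; cohort-level inference is
therefore the right granularity for pre/post comparisons.

## Model fitting

Two-stage maximum likelihood. Stage 1 estimates the shared initial weights
(w0_signal, w0_noise) on pooled data, profiling out each subject's five free
parameters by alternating optimization (two sweeps by default; per-subject
restart seeds derive from the data so the estimate is order-invariant).
Stage 2 fixes w0 and fits (α_w, α_c, β, λ, σ_c) per subject by Nelder–Mead
in transformed space (log for the positive parameters, logit for α_c) with
10 Latin-hypercube restarts, NLL tolerance 1e-6. The inner likelihood
recursion is sequential and JIT-compiled; a pure-Python path through the
model produces identical values and is cross-checked in the tests against an
independently coded per-trial recursion.

**Identifiability at desk scale.** β, λ and σ_c shape every trial's
likelihood and recover extremely well from single sessions (rank
correlations ≈ 0.95 in our 30-subject recovery study). The learning rates do
not: at α_w near 0.0018 the cumulative weight drift over 432 trials is ~4%
of the initial weights, shifting the certainty readout by ~0.01 against
report noise of σ_c ≈ 0.18, so the likelihood is nearly flat in α_w — and
α_c, which acts only through α_w-scaled updates, inherits that flatness.
Recovery of the learning rates from sessions of this length should not be
expected; distinguishing learning-rate hypotheses requires either much
longer sessions or effect sizes well above this operating point. The NLL
does behave as a proper local minimum at the generating parameters on long
(5,000-trial) sessions.

## Synthetic observers

The observer replaces the image→filter path with a rectified-Gaussian
surrogate: designated-orientation raw energy ~ max(0, N(floor + gain·c_p,
sd)) and opposite-orientation ~ max(0, N(floor, sd)), independent across
trials (floor 0.3, sd 0.15). The gain default (0.1016) is frozen from the
package's own bisection calibration so the default observer scores ≈80%
correct at 8% contrast — the training operating point. Choices and
confidence then come from the learning model itself, which is what makes the
correct/incorrect energy asymmetry and the confidence–accuracy relation
emergent rather than built in. Generative parameters default to learning
rates at the reported cohort medians (α_w = 0.0018, α_c = 0.533), β = 7,
λ = 2, σ_c = 0.18, initial weights (0.5, 0.1).

`simulate_experiment` assembles the full protocol — pre-test (both axes),
a 48-trial adjustment run seeded at the pre-test threshold, nine training
runs of 48 trials with a free-running weighted staircase on half the trials
and the adjustment-run endpoint contrast on the interleaved constant half,
then the post-test — with the model state carried continuously (a flag can
freeze learning during test sessions). Event times draw fixation and
post-stimulus intervals uniformly on 2000 ± 1000 ms. Everything is bit-exact
reproducible from (spec, design, seed); cohorts fan per-subject seeds out of
a master seed.

What the surrogate does *not* emulate: spatial uncertainty and eye
movements, energy correlations across trials (e.g. adaptation), axis- or
orientation-specific sensitivity differences, lapses, response times, and
any nonstationarity of the report noise. Passing tests therefore certify the
model's internal logic and the pipeline's statistics under these idealized
conditions, not behavioral realism beyond them.

## Analyses

* **Calibration curve** — trials sorted by confidence; a window of
  ceil(0.05·n) trials slides in steps of one trial; each window contributes
  its mean confidence and proportion correct.
* **Perceptual learning index** — OLS residuals of (post − pre) thresholds
  on pre, negated so larger = more learning; zero-mean and uncorrelated with
  baseline by construction.
* **Run slopes** — least-squares slope of per-run means against run index,
  used for thresholds and for the signal/noise weight trajectories.
* **Fisher-z group test** — atanh-transformed per-subject correlations,
  one-sample t against zero (degenerate all-equal samples handled
  explicitly).
* **BOLD simulation** — 240 samples at 10 Hz spanning −4…+20 s around
  stimulus onset; +1 impulse at trial onset (−2 s), ±1 or 0 at stimulus
  onset by prediction-error sign; convolved with a canonical double-gamma
  HRF (peak 6 s, undershoot 16 s, unit dispersions, peak:undershoot 6:1,
  scaled to unit peak on a dense grid so the scale is sampling-independent;
  kernel span 32 s). The anticipatory component peaks 4–6 s after trial
  onset. Since the exact HRF parameterization of any given analysis package
  varies, shape assertions are qualitative (peak window, deflection sign),
  not sample-exact.
* **Parametric regressors** — mean-centered weighted impulse trains at trial
  onsets (expected confidence) and stimulus onsets (prediction error),
  HRF-convolved on a 0.1 s grid and sampled at TR = 2 s.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances while remaining desk-scale: staircase
convergence at 100 seeds × 2,200 trials; parameter recovery at 30 subjects ×
432 trials; learning-signature and threshold-improvement checks at 20 seeds;
energy/correctness and calibration checks at 2,000–5,000 trials.
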