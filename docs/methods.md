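# Methods

This note records the models implemented in `g4fold`, the assumptions
behind them, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Two-state trajectory model

A molecule's conformation is a continuous-time Markov chain with two
states, low-FRET (unfolded or compacted) and high-FRET (folded G4), with
rates k_lh and k_hl in s⁻¹. The chain is sampled at the camera frame
interval Δt: the state is held constant within a frame and switches
between frames with probability 1 − exp(−kΔt). No motion blurring of E
across a frame is modeled; at the regimes of interest (kΔt ≤ 0.015)
within-frame transitions are rare and frame-resolved analysis is
standard.

Per frame, the apparent efficiency is the state mean (e_low, e_high)
plus Gaussian state noise (sigma_e_low/high, default 0.05 — typical for
surface-TIRF E distributions). The donor receives (1−E)·i_total and the
acceptor E·i_total counts on top of channel backgrounds, plus additive
Gaussian read noise per channel. Shot noise, donor–acceptor crosstalk,
gamma factors and triplet blinking are not modeled; they change the
absolute E scale, not the two-state statistics the estimators consume,
so passing recovery tests here says nothing about absolute-accuracy
corrections on real data.

Photobleaching is one exponential lifetime per fluorophore with a
single-step intensity change: acceptor bleach collapses the acceptor to
background and hands its share to the donor (the classic anticorrelated
step); donor bleach collapses both channels.

The initial state is drawn from the stationary distribution
k_lh/(k_lh+k_hl) unless `p_init_high` is set. It is a free parameter
because real samples can start far from equilibrium: in-situ refolded
samples show far fewer folded molecules than the rates imply, and
early-frame histograms then reflect the preparation, not the
equilibrium. The consistency ratio reported by the energetics stage
(K_eq from rates over K_eq from fractions) makes this visible instead of
hiding it.

## Trace processing

- Backgrounds are supplied constants or, per ensemble, the median of
  post-donor-bleach frames of molecules whose donor bleaches.
  Background-corrected counts may go negative; E is not clipped and the
  histogram range extends to [−0.1, 1.1], because clipping skews the
  Gaussian population fits.
- Validity threshold: frames with total intensity below 10% of the
  ensemble-median total are marked invalid (no threshold is standard;
  this one scales with the data).
- Photobleach detection: acceptor bleach is the largest single-frame
  acceptor drop exceeding 5× the robust frame-to-frame noise SD (MAD of
  first differences), with a donor rise of at least half the drop within
  ±1 frame, after which the acceptor median stays below 25% of its
  pre-step median. The collapse condition is essential: a high→low
  conformational transition produces the same anticorrelated step but
  leaves the acceptor at the low-state level, and without it every
  unfolding event would truncate the trace. Donor bleach is the largest
  total-intensity drop after which the total stays below 25% of its
  pre-step median.
- Per-molecule FRET value: mean of the first 15 valid frames (the
  convention for population histograms; applied per-frame at either
  100 or 300 ms integration). Molecules with fewer valid frames are
  excluded from histograms (logged) but retained for dwell analysis.

## Population decomposition

The one- or two-Gaussian model is fitted to histogram counts at bin
centers by least squares (histogram bin 0.02 E units), which is how such
histograms are conventionally presented and fitted; fractions are
percent areas a_i·σ_i / Σ a_j·σ_j. A direct maximum-likelihood mixture
fit on the raw values (scikit-learn) is kept as an independent
cross-check and agrees within ±3 points on n ≥ 500 fixtures.

Least-squares mixtures have a well-known local-optimum failure mode:
both components park on the majority mode. The fit is therefore
multi-started deterministically from (a) the two largest well-separated
local maxima of the lightly smoothed histogram and (b) value quantiles,
keeping the lowest-residual solution. Component SDs are bounded below by
half the bin width.

Model selection (1 vs 2 components) uses a nested-model F-test at
α = 0.01 plus two identifiability guards: fitted means must be separated
by more than the wider component SD, and both components must carry at
least 5% of the area. The guards reject degenerate splits (a narrow
spike on one noisy bin) while keeping genuine few-percent minority
populations.

## Dwell kinetics

States are assigned by thresholding at the midpoint of the two fitted
means, after an optional (default-on) 3-frame median filter; hysteresis
bands are available but off by default. Maximal runs become dwells;
duration = run length × Δt; the first and last dwell of each molecule
are censored (their true length is unknown). Minimum dwell is one frame;
no missed-event correction is applied, since kΔt ≪ 1 here. The
discretization bias of the embedded chain is below kΔt/2 and is
documented rather than corrected.

Three rate estimators:

- **histogram** (default of `fit_dwell_rate`): least-squares fit of
  A·e^(−kt) to the histogram of complete dwells, bin = 2 frames — the
  conventional presentation;
- **mle**: k = 1/mean(complete dwells), SE = k/√n — the closed-form
  oracle the histogram fit is tested against;
- **occupancy**: k = (observed transitions out of the state)/(total time
  in the state), counting censored dwells' time — the Markov
  maximum-likelihood estimator under censoring.

The first two use complete dwells only and are strongly length-biased
whenever the mean dwell is comparable to the observation window (a slow
folder in a 90 s trace: almost no complete low dwells exist, and those
that do are short by construction; measured bias exceeds 3× at
k_lh = 0.011 s⁻¹, 300 frames × 0.3 s). The occupancy estimator is
unbiased in that regime (recovery 0.0110 ± 0.0009 across seeds), so
workflows report it as the headline rate while still emitting all three.

Equilibrium energetics: K_eq = p_high/p_low or k_lh/k_hl and
ΔG = −RT ln K_eq at 293.15 K (room temperature) by default, R in
kJ·mol⁻¹·K⁻¹. Fractions of exactly 0 or 100 yield infinite |ΔG|,
reported rather than raised. Barrier heights are out of scope.

## CD analysis

- Smoothing: Savitzky–Golay, window 11 points, order 3 (windows 9–15
  leave the topology call unchanged on the test fixtures).
- Topology rules operate on genuine local extrema of the smoothed
  spectrum above a noise floor of 5× the robust SD of the smoothing
  residual, found on the full spectrum so one band's tail cannot count
  as a second band. Windows bracket the canonical landmarks: positive
  255–270 nm and negative 235–248 nm → parallel (absent any positive
  band ≥ 285 nm); positive 285–300 nm with negative 255–270 nm →
  antiparallel; positive in both 255–270 and 285–300 → hybrid or
  mixture; nothing above the floor → undetermined. The call is invariant
  to positive rescaling.
- Kinetic fits use the saturating exponential forms above in the time
  unit of the input; rates are reported per that unit (per minute for
  typical mixing traces). Auto model selection takes the two-phase form
  only when the F-test is significant at α = 0.01 and b/d ≥ 3 — at equal
  rates the two-phase form is unidentifiable (it collapses to a
  one-phase curve with amplitude a + c).
- Melting uses the Boltzmann sigmoid; linear sloping baselines are not
  fitted by default (the synthetic curves have flat baselines; real
  curves with strong baseline slopes will need them). A fit whose
  amplitude does not exceed 3× the residual SD is flagged
  non-converged (no resolvable transition).

## Binding

The depletion quadratic is the default isotherm even though 20 nM
labeled DNA barely depletes a micromolar binder, so the same code stays
valid for tight binders; the plain hyperbola is an option.
`saturation_reached` is False when the fitted bound-state plateau lies
more than 20% of the response amplitude above the largest observed
response — the signature of a series truncated below saturation, as
happens for weak binders titrated only to ~2× K_D. The CSP outlier rule
(mean + 1 SD) is the conventional cutoff for calling maximal
perturbations.

## Synthetic-data defaults as study conditions

Generator defaults encode the experimental design the analyses assume:
frame intervals 0.1/0.3 s; 300 frames per molecule; state means
0.49/0.85 with per-frame SD 0.05; rates 0.011/0.050 s⁻¹; ~1000
counts/frame with background 50 and read noise 20 per channel; melting
scans 25–95 °C at 0.5 °C steps with transition width 4 °C and 2%
amplitude noise; titrations as 16-point 1:1 dilutions from 200 µM with
20 nM labeled DNA and 1% response noise. i_total, backgrounds and read
noise are not tied to a specific instrument; they are set so the
per-frame E noise, not counting noise, dominates — the regime the
estimators are designed for.

## Problem sizes and replication

Recovery tests and the acceptance script run at desk scale: ensembles of
200 molecules × 300 frames, population cohorts of 150–300 molecules,
141-point melting curves, 16-point titrations. One simulated ensemble
carries Monte-Carlo error comparable to some published uncertainties
(≈0.004 s⁻¹ on the unfolding rate; ≈3.5 points on a 300-molecule folded
fraction), so headline quantities are reported as the mean over a few
independent replicate simulations (three ensembles for rates, five
cohorts elsewhere), i.e. the estimator's central recovery rather than a
single draw. Sub-seeds are derived arithmetically from the top-level
seed; everything is bit-reproducible given that seed.

## Known limitations

- Two states only; no hidden-Markov inference, no transition-path
  analysis, no >2-component mixtures.
- The occupancy rate estimator assumes memoryless (exponential) dwells;
  heterogeneous or aging kinetics would bias all three estimators.
- Topology classification is rule-based on band positions; it does not
  deconvolve spectra into basis fractions and cannot distinguish a true
  hybrid fold from a parallel/antiparallel mixture.
- The melting fit is a two-state sigmoid without van't Hoff analysis;
  T_m is the only thermodynamic readout.
- Bleach detection expects single-step photophysics; gradual
  photobrightening/quenching or multi-step bleaching would evade the
  step rules.
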