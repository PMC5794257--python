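# Methods

## Forward model and simulation

The cell is the standard three-element patch-clamp circuit: series (access)
resistance Rs feeding the parallel pair of membrane resistance Rm and
time-varying membrane capacitance Cm(t).  The command is a step protocol with
a dual sinusoid superimposed: frequencies f1 and f2 = 2·f1, with the 40 mV
"dual sinusoid" budget split equally (20 mV per frequency; configurable).
f1 defaults to 5 kHz (0.2 ms Cm resolution, inside the 0.16–0.32 ms period
range the protocol family uses) sampled at 200 kHz, an integer number of
samples per period.

Integration uses the exact exponential update of the one-state ODE
`Cm dVm/dt = (V−Vm)/Rs − Vm/Rm` per sample, with the sinusoidal forcing
integrated analytically over each sample interval.  Because the update is
exact for the actual continuous-time command, the sampled current equals the
continuous solution at sample instants to machine precision; this is what
lets the estimator recover Cm/Rs/Rm to float tolerance on noiseless sweeps
and gives the test suite a closed-form admittance oracle.  Cm(t) is held
constant within a sample (it changes by < 10⁻⁶ relative per sample at the
release rates simulated).  The scan is JIT-compiled with numba when present;
a blocked cumulative-product NumPy fallback is used otherwise.

The Ca²⁺ current is a steady-state Boltzmann conductance
`I = g_max · m∞(V) · (V − E)` with `m∞(V) = 1/(1+exp((V½−V)/s))`, V½ = −34 mV
and slope 7 mV (a field-typical value; the slope is not part of the study
conditions).  It is evaluated on the **sine-free** command: kHz gating of a
steep nonlinearity under a 40 mV sine would inject a large second harmonic
exactly at f2 and corrupt the admittance, whereas real channel gating is
low-pass relative to the probe.  With this convention the f1/f2 response is
purely passive, the admittance invariant holds to 0.1%, and the Ca current
appears in the sine-free residual where the analysis expects it.

The exocytosis ground truth ΔCm(t) is phenomenological: zero until the
release latency, a linear ramp (rate, capacity), an additional superlinear
ramp from its onset (rate, capacity), and a single-exponential return toward
baseline after the step (endocytosis τ).  No vesicle-pool state model is
implied.

### Preset calibration

The WT/KO presets encode the study conditions (10 pF / 10 MΩ cell, −84 mV
holding, 1 s steps, latencies 102/204 ms, linear 52 fF at 101 fF/s,
superlinear 223 fF, endocytosis τ 6/7 s, EPSC peak rates 57/44 s⁻¹,
time-to-peak 21/9 s, small-peak weights 1/5.5%, small-slow fractions
0.44/1.9%, median amplitudes ~173/212 pA).  Two derived calibrations:

- The four values {52 fF, 101 fF/s, 223 fF, 256 fF/s} are population means
  that cannot coexist in a single 1 s trace (52/101 + 223/256 ≈ 1.39 s of
  ramp time in ≤ 0.9 s).  The WT preset keeps the latency, the linear rate
  and both magnitudes, places the superlinear onset where the linear
  component saturates (0.617 s) and derives the superlinear ramp rate
  (582 fF/s) so the full 223 fF fits inside the step.
- `g_max_ca` is set so the linear-component Ca²⁺ efficiency at the preset
  step equals the stated 0.9 (WT) / 0.93 (KO) fF/pC — the efficiency is a
  study condition, the conductance is the free parameter that realizes it.

EPSC trains are inhomogeneous Poisson: baseline rate until the high-K⁺
switch, linear rise to the peak over the time-to-peak, then exponential
relaxation (τ = 20 s) toward a plateau — 50% of peak for sustained fibers,
zero (τ = 4 s) for transient ones, chosen so sustained WT runs integrate to
~1.8·10³ events over 50 s and transient runs fall below 5% of peak by the
20 s horizon.  Events are difference-of-exponentials (rise 0.15 ms, decay
0.45 ms; the small-slow subpopulation decays at 1.5 ms and is drawn among
the small-amplitude events).  The KO main amplitude body is gamma(6, 38 pA)
— it reproduces both the 212 pA median and the ~8% of events above 350 pA —
while WT uses a Gaussian body per the double-Gaussian convention.

What the generators do **not** emulate: vesicle depletion/refractoriness
(trains are exactly Poisson, i.e. slightly overdispersed relative to real
sustained release), stochastic channel gating, seal/access drift, line
noise, and any cochlear mechanics behind the ABR/DPOAE waveforms (signals
are injected at programmed amplitudes with white noise).  Passing tests
therefore certify the estimators against the stated generative model, not
against every artifact of real recordings.

## Dual-sine estimator

Per f1 period the DFT coefficients of command and current at one and two
cycles/period give Y1 and Y2; writing Z = 1/Y, the identity
`Re 1/(Z1−Rs) = Re 1/(Z2−Rs) = 1/Rm` reduces to a quadratic in Rs (solved
with the numerically stable form; the admissible root satisfies
0 < Rs < min Re Z), after which `1/(Z−Rs) = 1/Rm + jωCm` reads off Rm and
Cm at both frequencies (averaged).  Windows whose admittance pair admits no
passive triple are flagged invalid, never clamped, and invalid windows
propagate as gaps.

Periods overlapping a command discontinuity are dropped for 6 periods (the
charging transient τ = Cm·Rs∥Rm ≈ 0.1 ms is only e⁻² down after one 0.2 ms
period; after six it is below 0.02 fF equivalent).  ΔCm is referenced to the
mean of a pre-step baseline window.  Baseline aggregates (Cm, Rs, Rm, DC
current) use medians: the per-period inversion noise on Rm is heavy-tailed
and biases means.

The sine-free residual current is each period's DC coefficient minus a
passive-leak prediction anchored at the baseline (I0 + ΔV/(Rs+Rm)); its
cumulative magnitude over the step is Q_Ca (inward current negative, charge
reported positive).  Dropped periods borrow the nearest valid residual for
the integral so edge transients are not booked as Ca charge.

## Exocytosis analysis conventions

- **Latency**: first crossing of baseline mean + 3 SD sustained for 5
  periods, with an absolute floor of 0.02 fF so the rule is defined on
  noiseless tracks (the floor contributes < 0.3 ms bias at the preset
  rates).  An optional centered boxcar (`smooth_periods`) makes the rule
  usable on noisy tracks, where the raw per-period SD (tens of fF) would
  push the threshold far up the ramp; smoothing is off by default because a
  centered boxcar slightly advances the crossing at a noiseless kink.
- **Segmentation**: continuous two-segment linear fit over
  [latency, step end]; the changepoint is found by exhaustive search over
  period indices using suffix-sum normal equations (O(n) per candidate set,
  exact and reproducible).  The second segment is accepted by an F-test at
  α = 0.01 whose p-value is Bonferroni-corrected by the number of candidate
  changepoints — the naive test is anti-conservative because the changepoint
  is chosen by minimizing SSE (measured false-positive rate ≈ 4% at nominal
  1% without the correction).  Component magnitudes are read off the fitted
  curve referenced to the pre-step baseline (ΔCm = 0), so a late-biased
  latency estimate does not truncate them; the reported rates are the
  observed segment slopes.
- **Efficiency**: ΔCm/ΔQ_Ca over the linear-component window with endpoint
  values taken as medians over ±15 periods (centered, so ramps add no
  first-order bias).
- **Endocytosis**: `A·exp(−t/τ)` fit of post-step ΔCm (log-linear seed,
  nonlinear refinement); a non-decaying tail reports absent.
- The Cm–V relation uses the saturating form Y0 + A1·(1 − exp(−(x−x0)/t))
  for x ≥ x0 — the form consistent with A1 being an asymptote and x0 the
  first-release voltage; the literal decaying exponential is available via
  `form="literal"`.  The onset-voltage histogram is fitted with
  Y0 + (A/(w√(π/2)))·exp(−2((x−xc)/w)²), so w equals twice the SD of the
  matching normal density.

## EPSC analysis conventions

Detection correlates the negated trace with a unit-energy
difference-of-exponentials kernel, thresholds peaks at 5 robust noise SDs
(MAD of first differences; 10 pA absolute floor), and refines each candidate
on the raw trace within one template-peak lag — narrow enough that
neighbouring events are not merged.  Amplitude is the 3-point-smoothed peak
minus a local pre-onset median baseline (the smoothing removes most of the
select-the-max noise bias).  Decay τ is a single-exponential fit over the
30%→5% falling phase — late enough that the rising exponential no longer
contaminates the tail (fitting from 70% inflates τ of the default template
by ~4%).  Duration is onset to 90%-completed decay; events with a neighbour
inside their decay span are flagged not-simple; small-slow means amplitude
< 100 pA and τ > 1 ms.

Rate profiles count events in 1 s windows at 100 ms stride; threshold rules
quote the trailing edge of the first qualifying window.  Because overlapping
windows keep a chance baseline cluster above threshold for up to
window/stride windows, onset requires the crossing to persist for
window/stride + 2 consecutive windows.  Detection lag on a rate jump is the
wait for enough events to exceed the criterion (Gamma-distributed), so the
onset is calibrated as a median-over-seeds statistic, not a per-seed
guarantee.  Time-to-peak computes its spontaneous statistics on the same
200 ms windows the rule uses.  Sustained means the rate exceeds baseline
+ 2 SD in ≥ 50% of windows beyond onset + 20 s.

A known property, left uncorrected by design: the **maximum** of the sliding
1 s-window rate estimate is an upward-biased statistic of a Poisson train
(max over many correlated Poisson counts).  With the programmed WT peak of
57 s⁻¹ the measured mean maximum sits near 69 s⁻¹ (+20%).  The profile
window/stride and the max rule are fixed conventions here, and the generator
keeps the stated 57 s⁻¹ as the underlying peak, so this bias is reported
rather than calibrated away.

Amplitude mixtures are fitted by EM for both sanctioned models — small
Gaussian + Gaussian and small Gaussian + gamma (the smaller-mean component
is always the Gaussian; gamma M-step solves the weighted shape equation by
Newton on ln k − ψ(k)) — and selected by BIC; fits are refused below 100
events, and a mixture that does not beat the best single-component model by
BIC is flagged effectively single.  The small-peak area is the integrated
weight of the small component, in percent.

## ABR / DPOAE conventions

ABR epochs are zero-phase band-passed (2nd-order Butterworth, 300–3000 Hz)
and trial-averaged; the residual noise floor is the RMS of the pre-stimulus
segment.  Wave 1 is the window maximum (default 1.0–2.5 ms) and the
following trough.  Since a max-minus-min picker reads ~3.5 noise SDs even
from pure noise, the mean peak-to-peak amplitude of a matched-length
stimulus-free window late in the epoch is subtracted from every p1–n1 before
thresholding; this is what makes the no-response → 80 dB default rule fire
reliably.  The threshold criterion is multiplier × RMS noise floor
(default 5) — the reading on which "five standard deviations above the noise
floor" and "5× the RMS noise floor" coincide for a zero-mean floor — applied
to the monotone (running-maximum) piecewise-linear interpolation of the
growth function; a mean + k·SD mode is available.

DPOAE records are 1 s at 200 kHz (1 Hz bins, integer-cycle primaries); the
distortion product is the single-bin FFT magnitude at 2f1−f2, the noise
floor the mean of the 20 adjacent bins (10 per side, DP bin excluded,
primaries excluded), and the threshold the interpolated level where the DP
exceeds floor mean + 3 SD.  Extraction refuses non-integer bins and DP/primary
bin collisions.

## Problem sizes and determinism

All randomness flows from per-call `numpy` generators seeded by a
deterministic fan-out of one root seed; equal seeds give bit-identical
outputs, and the pipeline manifest records the config hash and seed.
Default analysis sizes: 22 s sweeps at 200 kHz for the capacitance chain
(one f1 period = 0.2 ms ⇒ ~105 000 Cm samples), 20-seed ensembles for
stochastic EPSC statistics, 50 × 1000 draws for the mixture recovery, and a
5×5×5 parameter grid for the RC-inversion identity.
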