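# Methods

## The channel model

`kvclamp` models Kv11.1 as a two-gate Hodgkin–Huxley channel. The membrane
current of a voltage-clamped oocyte expressing the channel is

    I(t) = b · g_max · n(t) · r(t) · (V − E_rev) / 1000        [µA]

with `g_max` in µS, potentials in mV, `n` the activation gate, `r` the
inactivation (availability) gate and `b` a concentration-dependent block
factor. Both gates relax first-order toward Boltzmann steady states,

    n∞(V) = 1 / (1 + exp((V½,act − V)/k_act))        (increasing)
    r∞(V) = 1 / (1 + exp((V − V½,inact)/k_inact))    (decreasing)

with voltage-dependent time constants

    τ(V) = τ_min + τ_amp / (exp((V−Vp)/s_depol) + exp(−(V−Vp)/s_hyper)),

a bell-shaped form that is strictly positive and lets the two limbs be
tuned independently. Within a constant-voltage epoch the relaxation is
integrated in closed form (`x(t+dt) = x∞ + (x−x∞)·e^(−dt/τ)`), so simulated
sweeps carry no integration error; tests verify agreement with a
brute-force explicit integrator at a 1000× finer step to <0.1%.

Bi-exponential deactivation — the hallmark slow, two-component closure of
Kv11.1 tails — is produced by an optional second activation-gate
population sharing `n∞(V)` but relaxing with
`τ_slow(V) = τ_act(V) + excess(V)`, where the excess is a bell centered in
the deactivation voltage range (−85 mV). Both populations are therefore
kinetically identical at test potentials (a single activation time course,
as observed) and diverge only where deactivation is measured. The observed
fast fraction is a logistic weight `w_fast(V)` decreasing with
depolarization, so the fast component dominates at more hyperpolarized
potentials.

Drug block is a voltage- and state-independent Hill scaling
`b = 1/(1+(c/IC50)^h)`; KCNE2 co-expression is a pure conductance scaling
`g_max → (1−f)·g_max` with gating untouched, the simplest mechanism
consistent with an amplitude-only effect. Measurement noise is additive
Gaussian per sample plus an optional Ohmic leak conductance.

## Parameter provenance

Each packaged set (`presets/*.yaml`) mixes two kinds of values:

- **Measured constants** (from TEVC characterization of the clones):
  equine V½,act = −17.3 mV, k_act = 8.1 mV, G = 159 µS, E_rev = −103 mV;
  human V½,act = −14.2 mV, k_act = 9.6 mV, G = 234 µS, E_rev = −104 mV;
  KCNE2 steady-state reduction 42.3%; terfenadine IC50 0.42 µM
  (steady-state readout) / 0.37 µM (tail readout), Hill coefficient 1.
- **Calibrated shapes** (flagged `not-from-experiment` in the YAML): the
  inactivation Boltzmann and every τ surface. Published characterizations
  report these only graphically, so the packaged values are a
  self-consistent calibration chosen once so that the model reproduces the
  qualitative fingerprint and the analysis assumptions hold:

  1. the steady-state I-V is bell-shaped with its maximum at 0 mV;
  2. availability is ≈1 across the −120..−90 mV window, so the linear
     tail fit recovers `g_max` (this forces V½,inact = +3.5 mV,
     k_inact = 20 mV — a phenomenological availability curve, not a
     micro-scale inactivation measurement);
  3. recovery from inactivation at tail potentials (τ ≈ 0.6–1 ms below
     −90 mV) is ≫ faster than deactivation there (τ_fast ≈ 250–700 ms),
     so the hook peak of the tail reads out `g·n·r∞·(V−E_rev)`; this is
     what makes "peak tail ∝ activation" and "R ≈ availability" exact
     identities rather than approximations (tests: 2% and 2 mV);
  4. activation τ ≈ 300 ms at 0 mV, and epoch durations are ≥4–5
     relaxation times at the relevant voltages so steady state is reached
     (4 s steps, 2 s full activation, 8 s deactivation tails, 10 s
     inter-sweep interval at holding);
  5. inactivation-onset τ decreases with depolarization over the
     −20..+40 mV test range (equine 1.6–8 ms, human uniformly 1.5× faster,
     preserving the species contrast at every voltage).

  Activation kinetics are shared between the species sets, matching the
  absence of a measurable difference in activation time constants.

Sampling is 2 kHz throughout. Sweeps start from gate equilibrium at the
holding potential; the default inter-sweep interval is long enough that
this is exact to <1e−5.

## Analysis conventions

- **Exponential fits** use `scipy.optimize.curve_fit` with log-linearized
  initial guesses (bi-exponential: peeling), relative tolerance 1e−8, at
  most 10⁴ evaluations. Non-convergence is flagged, never silent; flat
  traces raise a degenerate-fit error. Bi-exponential results whose time
  constants differ by <1.5× or whose smaller amplitude is <1% of the total
  are flagged `effectively_monoexponential`.
- **Capacitive blanks**: 2 ms (tail peaks), 1 ms (inactivation onset),
  5 ms (deactivation) skip the step transient at finite sampling.
- **Activation τ table** fits the first 500 ms of the step, −20..+20 mV
  only; at higher voltages the overlap with inactivation makes a single
  exponential a poor description, and the fitted values at all voltages
  conflate the two processes.
- **Onset τ** uses a two-pass window: a 20 ms first pass sets the scale,
  the final window is ~3 fitted time constants — long enough for 95% of
  the decay, short enough that slow deactivation drift does not bias τ
  (recovery within ~8% noiseless at every test voltage).
- **Linear tail fit** defaults to −120..−90 mV (the window on which the
  reported conductances are defined); the window is a parameter because an
  alternative −110..−90 mV convention exists, and both agree within 3% on
  clean data.
- **Tail normalization** divides by the largest-magnitude tail across
  sweeps of one simulated cell (per-replicate, not pooled).
- **Rectification** excludes voltages within 5 mV of E_rev (vanishing
  driving force) and fits a decreasing Boltzmann with a free normalization
  constant.
- **Noisy tail amplitudes**: picking a sample extremum on a noisy sweep is
  upward-biased (it selects favorable noise), which visibly shifts the
  activation midpoint at σ ≈ 0.1 µA. `method="hook_fit"` instead regresses
  the full hook waveform `C + A·e^(−t/τd)·(1−e^(−t/τr))` and reports the
  fitted curve's extremum — regression-only, hence unbiased under noise.
  The pipeline switches to it automatically when noise is configured; the
  default extremum estimator is exact on clean sweeps.
- **Dose-response** fits `1/(1+10^(h·(log c − log IC50)))` on
  log-transformed concentration — the two-parameter reduction of a
  four-parameter logistic with top 1 and bottom 0, exact for currents
  expressed as `I_drug/I_control`. The Hill coefficient may be fixed.
- **Replicates** are reported as mean ± SEM after removing at most one
  value farther than 3 sample-SD from the mean of the full set.

## The wedge generator

The ventricular-wedge module is phenomenological by design: multicellular
preparations report APD90 and capture outcomes, not channel states, so the
generator makes exactly those quantities its ground truth. Baseline
restitution is `APD90(BCL) = apd_max − a·e^(−BCL/τ_rest)` with
apd_max = 480 ms, a = 400 ms, τ_rest = 750 ms — yielding ≈452 ms at
2000 ms BCL and ≈194 ms at 250 ms BCL, plausible ventricular values. The
drug arm multiplies APD90 by `1 + prolongation(BCL)` with the map
{4000: 0.20, 2000: 0.17, 1000: 0.12, 500: 0.06, 333: 0.04}; only the
2000 ms entry is an experimentally reported value, the others shape the
reverse rate dependence (larger prolongation at slower pacing expected
when a repolarizing current is blocked). A stimulus fails when its
interval since the last upstroke is below APD90 plus a 60 ms refractory
margin; with these defaults the drug arm loses capture at 250 ms BCL while
still capturing at 333 ms, and the control arm sits just past the capture
boundary at 250 ms (193.5 + 60 = 253.5 ms > 250 ms), mirroring the
borderline control behavior of real wedges at that rate.

Beats are a sigmoidal upstroke (2 ms) × sigmoidal repolarization (width
12 ms) placed so the 90% crossing lands exactly at the target APD90.
APD measurement is generator-independent: upstrokes from dV/dt maxima,
per-beat baseline and peak, threshold crossing at the requested level; it
inverts the generator within one 0.5 ms sample at every cycle length.

## What the synthetic data do and do not show

The simulator reproduces the structure the analyses assume: Boltzmann
gating, first-order kinetics, multiplicative block, additive noise. Tests
that recover parameters from these data therefore validate the *analysis
chain* (protocols → measurement → fits), not the biological fidelity of
the model. Real TEVC recordings additionally contain endogenous oocyte
conductances with their own kinetics, series-resistance and clamp-speed
artifacts, capacitive transients, run-down/run-up drift, temperature
sensitivity, and state-dependent (open-channel) drug block with onset
kinetics — none of which are modelled beyond an Ohmic leak and Gaussian
noise. Likewise the wedge generator contains no transmural heterogeneity,
no true restitution memory and no arrhythmia dynamics.

## Known limitations

- The inactivation-gate parameters are a phenomenological availability
  curve calibrated to the rectification analysis, not measured constants;
  they should not be compared against micro-scale inactivation V½ values.
- Deactivation "populations" are a descriptive device for bi-exponential
  tails; no Markov-state interpretation is intended.
- Activation-τ tables conflate activation and inactivation by design
  (they fit the observable current, as the standard analysis does).
- Problem sizes in the tests and acceptance script (11–17 sweeps at 2 kHz,
  4–10 s sweeps, ≤20 noise replicates) match the scale of the real
  experiments and keep the full suite in the seconds-to-minutes range.
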