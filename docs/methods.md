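# Methods

## The model

Each heart motor neuron (HE) is a seven-compartment cable: soma → three
serially connected primary neurite compartments → axon, with a passive
secondary neurite branching off the first primary neurite and a synaptic
compartment hanging off the secondary neurite.  Channel placement follows
compartment class: the delayed rectifiers K1 (fast) and K2 (slow) in soma,
primary neurites and axon; the transient A-current KA in neurites and axon;
persistent sodium P, slow calcium CaS and calcium-dependent potassium KCa
in the primary neurites; fast sodium Na only in the axon.  The secondary
neurite and synaptic compartments are passive.

Maximal conductances are parameterized as percentages of per-compartment
ceiling values on a 2–100% grid in 2% steps (Na 3500, P 9.5, CaS 0.5 S/m²;
K1/K2 25 soma / 375 neurite / 500 axon; KA 50 neurite / 750 axon; KCa 50;
electrical coupling ceiling 10 nS, treated as an absolute conductance).
The shipped reference instance uses soma K1 8%, soma K2 92%, neurite
K1 56%, K2 4%, KA 32%, P 18%, CaS 72%, KCa 4%, synE 22%, axon Na 76%,
K1 4%, K2 96%, KA 80%.

The ensemble contains two bilateral pairs (HE(8), HE(12) × left/right).
Bilateral partners are electrically coupled at their synaptic compartments
with conductance g_synE; the coupling current is computed from the shared
pre-step voltages, so the two partner currents are exactly equal and
opposite at every step.  HE(8) and HE(12) do not interact with each other.

### Channel kinetics

The kinetics are a generic Hodgkin–Huxley parameterization: sigmoid steady
states `1/(1+exp(−(V−V½)/k))` with integer activation exponents, optional
inactivation, bell-shaped (or constant) voltage-dependent time constants,
a first-order calcium pool charged by the CaS current, and KCa gated by
`Ca/(Ca+K_d)`.  All kinetic parameters live in the circuit configuration
(JSON-serializable, `schema_version` 1) and can be replaced wholesale.

The default kinetics were tuned so the reference conductance set produces
the qualitative regime the analysis assumes: the persistent sodium current
depolarizes the neurites, the axon fires tonically at ~5–7 Hz paced by the
slow delayed rectifier K2 (a relaxation cycle of spike → K2 activation →
repolarization → slow K2 deactivation), and the premotor inhibition —
summed at the synaptic compartment — silences firing during the premotor
burst, sculpting anti-phase motor bursts.  Somatic spikes are attenuated
axon spikes (~25–30 mV) riding on a 10–15 mV slow wave.  They are a
plausible default, not a fit to any recorded cell; analyses that depend on
exact leech kinetics should supply their own configuration.

### Passive parameters and geometry

The compartment areas (soma 6, primary neurites 3, secondary 1.5,
synaptic 1, axon 2 ×10⁻⁹ m²), specific capacitance 0.01 F/m², leak
1 S/m² (τ = 10 ms) at −60 mV, and the axial conductances (200 nS along the
primary chain, 150 nS to the axon, 60/50 nS on the synaptic branch) were
chosen so that axonal spikes reach the soma above the −20 mV detection
threshold while the synaptic-branch inhibition can silence the axon.  They
are configurable per compartment.

### Synapses

Premotor input is pure playback: a connection's conductance is the sum of
double-exponential kernels (rise 5 ms, decay 80 ms, unit peak) at the
presynaptic spike times, delayed by 20 ms per segment of separation
between the source and target ganglia, scaled by a single-factor
depression state (multiplicative decrement 0.1 per spike, exponential
recovery τ = 0.5 s) and by the connection strength
`unitary (25 nS) × w × ρ × σ`, with reversal −62.5 mV.  The unitary
conductance and reversal are design values (the sources print neither);
25 nS makes a full-weight input roughly strong enough for two to three
co-active inputs to pause firing, which yields duty cycles near 0.5.

### Integration

Gating variables advance by exponential Euler using steady states and
per-step decay factors tabulated on a 0.05 mV grid; voltages advance by a
semi-implicit trapezoid step (θ = ½, channel conductances frozen within
the step) solved by fill-in-free tree elimination over the compartment
tree.  The default step is 0.1 ms; burst-median phases change by
< 0.005 cycle when the step is halved.  Voltages outside ±200 mV raise an
instability error naming the time and compartment.  Simulations are
deterministic given inputs and step.

## Metrics

Spikes are upward crossings of −20 mV (height = peak minus the 2 Hz
zero-phase low-pass slow wave at the peak).  Bursts are maximal runs with
inter-spike intervals ≤ 1 s and ≥ 4 spikes; the median spike (mean of the
two middle times for even counts) marks burst phase.  Phase 0 of each
coordination is the ipsilateral HN(4) burst median; per-burst phases are
combined by a circular mean, and mΔφ = wrap(φ_HE8 − φ_HE12) into
(−0.5, 0.5].  The 18 optimized metrics are duty cycle, within-burst spike
frequency, slow-wave height and spike height per neuron and coordination,
plus one mΔφ per coordination; absolute phases are reported but never
optimized.  The first two input cycles are discarded; at least three
bursts per neuron must remain.

Errors are range-normalized, `(metric − target)/range`, with the standard
ranges duty 0.10, frequency 7 Hz, slow wave 5 mV, spike height 7.5 mV,
progression 0.06, phase 0.03; MAE is the maximal absolute error and
MAE < 1 (strict) defines a good model.

We define pmΔφ as the full phase spread of the premotor bursts (front-most
HN(3) minus rear-most HN(7) in our rear-to-front convention), which is the
quantity that upper-bounds mΔφ; the narrower HN(4)−HN(7) measure used in
some population summaries is exposed separately
(`PremotorPattern.pm_delta_phi_47`).

## Spike-triggered averaging

Offsets are aligned with a zero-phase 5–3000 Hz band-pass (second-order
Butterworth sections run forward and backward) rather than re-zeroing each
sweep at its trigger value, which is biased by coincident IPSCs from other
inputs.  Per presynaptic burst, 2 leading and 2 trailing spikes are
trimmed; sweeps whose −20…+80 ms window comes within 10 ms of a
postsynaptic escape spike are excluded automatically (the trim counts,
radius and window are parameters).  Sweeps from the peristaltic and
synchronous epochs are pooled.  The average is lightly smoothed (0.5 ms)
before measurement — selecting the largest point of an unsmoothed noisy
mean would bias weak amplitudes upward — and the amplitude is measured
from the local pre-peak baseline (a 1.5 ms average ending at the trough
between trigger and peak) to the largest positive (outward) peak in the
2–40 ms search interval; latency is trigger-to-peak.  Per motor neuron,
weights are normalized by the largest of its four inputs (max = 1); the
normalization basis is a package choice, as is measuring the same
(largest) peak in every preparation.

## The search

Objectives are `max(1, e²)` per metric (a smooth softplus variant exists
behind a flag).  The floor makes every model whose errors are all within
one target range map to the all-ones vector, which weakly dominates
everything; the search therefore stops refining metrics that are already
good enough.  The loop is NSGA-II style — fast non-dominated sorting,
crowding distance, binary tournaments, SBX crossover (η = 15), polynomial
mutation (η = 20, rate 1/n) — with conductance genes snapped to the 2%
grid, σ ∈ [0, 2], and each ρ bounded so the fitted strength w·ρ stays
within ±1 SD of its measured average (floored at 0).  Searches run in
batches from random initial conditions with per-batch seeds derived from
the spec seed; results are exactly reproducible.  Failed simulations and
silent models score a finite sentinel (10⁶) on every objective.

## Synthetic data

The pattern generator emulates the premotor structure: one burst per unit
per cycle (period 6 s, duty 0.55, 10 Hz), burst *medians* placed to
realize the requested spread (peristaltic 0.11, synchronous 0.02,
rear-to-front HN(7)→HN(3)), 10 ms spike jitter, per-unit mean-rate offsets
(±5%) and per-cycle rate variability (CV 5%) so the four units are not
artificially phase-locked at the firing period — real interneurons drift
by more than an interspike interval per burst.  The clamp generator plants
double-exponential IPSCs (rise 1.5 ms, decay 12 ms) of known per-source
amplitude with lognormal trial variability (CV 0.2), sinusoidal plus
random-walk drift (0.3 nA, 0.1 Hz), white noise (0.1 nA = 25% of the
largest default amplitude) and Poisson escape-spike artifacts (0.2 Hz), at
10 kHz.  Self-targets wrap the metrics of a simulated known model as an
animal's targets, planting a zero-error optimum for recovery tests.

What the generators do **not** emulate: electrode/amplifier artifacts
beyond drift and noise, inter-animal correlations of pattern and weights,
period changes between coordinations, or graded (non-spike-locked)
transmission.  Passing tests show the pipeline recovers what the
generators plant under realistic noise; they do not certify performance on
recorded data.

## Problem sizes

Tests and examples use reduced problem sizes chosen for tight feedback
loops: simulations of 6–8 cycles at 0.1–0.2 ms steps, searches of
300–2000 evaluations with population 30–50, STA fixtures of 10 cycles.
The search and cross-animal machinery accept the full-scale settings
(five batches × 1000–2000 evaluations, ≥ 5000 models) unchanged.

## Numerical choices and degenerate inputs

Burst phases use the previous reference median (ties: a reference median
exactly at a burst median counts as preceding).  wrap maps to (−0.5, 0.5].
Even-length bursts take the mean of the two middle spike times.  The
Pareto front uses component-wise ≤ with at least one strict <; duplicate
objective vectors are all retained.  Elitist survival orders by
(rank, −crowding, batch, index) so reduction is deterministic.  Zero-range
targets, off-grid percentages, non-increasing spike trains, all-zero
amplitude profiles, zero-variance regression predictors and all-identical
Kruskal–Wallis inputs raise typed errors rather than propagating NaNs.

## Known limitations

* The default kinetics are a tuned generic parameterization, not measured
  leech channel kinetics; absolute metric values (e.g. spike heights of
  ~29 mV vs ~15 mV in recordings) differ from biological traces, which is
  immaterial for self-target studies but matters for fitting real data.
* The σ/ρ decomposition is degenerate (σ can absorb a common factor of a
  motor neuron's ρ values); searches over both rely on the ρ bounds to fix
  the scale.
* Cross-source contamination limits STA accuracy for the weakest inputs
  (~5–9% at default noise); the reported SD envelope underestimates this
  correlated error.
* The explicit (not implicit) bilateral coupling restricts stability to
  g_synE·dt/C ≲ 1, amply satisfied at the 10 nS ceiling and default step.
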