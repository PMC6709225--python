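# leechheart

Modelling and analysis of the leech heartbeat motor circuit: why does each
animal's heart motor pattern look individually unique, and which parameters
— synaptic strengths or intrinsic membrane conductances — carry that
uniqueness?

The leech heartbeat is driven by a central pattern generator whose
inhibitory premotor interneurons HN(3), HN(4), HN(6) and HN(7) project onto
segmental heart motor neurons HE(8) and HE(12).  One body side beats
peristaltically (rear-to-front phase progression), the other nearly
synchronously, and the two sides swap roles periodically.  The functional
output of the circuit is the motor phase progression

&nbsp;&nbsp;&nbsp;&nbsp;mΔφ = φ(HE8) − φ(HE12),

the phase difference between the burst medians of the two motor neurons in
units of the cycle period, which is upper-bounded by the premotor phase
progression pmΔφ of the interneuron bursts.

This package provides, as a Python library:

* **`circuit` / `engine`** — a bilateral ensemble of four seven-compartment
  conductance-based HE motor neuron models (soma, three primary neurites,
  a passive secondary neurite, a synaptic compartment, an axon; channels
  Na, P, CaS, K1, K2, KA, KCa placed per compartment class), electrically
  coupled across the midline (g_synE) and driven by played-back premotor
  spike trains through depressing inhibitory synapses with conduction
  delays.  Maximal conductances are percentages (2–100%, 2% grid) of
  per-compartment ceiling values.
* **`metrics`** — burst analysis (first/last/median spikes, duty cycle,
  within-burst spike frequency, spike height, low-pass slow-wave height)
  and the 18-entry optimization metric vector with range-normalized errors;
  a model is *good* when the maximal absolute normalized error (MAE) is
  below 1.
* **`sta`** — spike-triggered averaging of IPSCs from voltage-clamp traces:
  band-pass offset alignment (5–3000 Hz), leading/trailing IPSC trimming
  per burst, exclusion of sweeps near escape spikes, largest-peak
  amplitude/latency measurement, and per-animal relative weights
  (max = 1 per motor neuron).
* **`optimize`** — a many-objective evolutionary search (NSGA-II style)
  whose objectives are fuzzy-truncated squared errors, `max(1, e²)`: every
  metric already inside its target range scores exactly 1, so the search
  concentrates on the metrics still outside range instead of breeding
  un-dominatable single-metric specialists.
* **`population`** — the synaptic strength index
  SSI = w(HN4→HE8)/w(HN4→HE12) + w(HN7→HE12)/w(HN7→HE8), cross-animal
  generalization tests of good models, the maximum-progression protocol
  (only HN(3)→HE(8) and HN(7)→HE(12) active at 4× strength), K2–P
  conductance correlations and Kruskal–Wallis weight comparisons.
* **`synth`** — generators for premotor patterns, voltage-clamp recordings
  and self-target profiles with known ground truth, so every stage of the
  pipeline is testable end to end without recorded data.

## Worked example

```bash
python examples/simulate_ensemble.py
```

builds the reference model, drives it with a synthetic pattern
(period 6 s, peristaltic premotor spread 0.11) and prints the 18 metrics,
ending with:

```
  HE8.peristaltic.duty_cycle                0.564
  HE8.peristaltic.spike_frequency           5.454
  ...
  peristaltic.m_delta_phi                   0.039
  ...
  synchronous.m_delta_phi                  -0.038
```

The positive peristaltic mΔφ (HE(12) leading HE(8)) is the rear-to-front
wave that pumps blood; the synchronous progression is near zero.  The other
examples demonstrate STA strength estimation on synthetic clamp data
(`sta_strengths.py`), the fuzzy-truncated multiplier search on a
self-target animal (`multiplier_search.py`), and the population analyses
(`population_analyses.py`).

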