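"""Synthetic premotor patterns, voltage-clamp recordings and self-targets.

These generators emulate the statistical structure the analysis pipeline
assumes so that every stage is testable without recorded data:

* premotor spike trains of the four interneurons with a rear-to-front phase
  progression in the peristaltic coordination and a near-zero progression
  in the synchronous one, bilateral by the mirror convention;
* voltage-clamp current traces containing IPSCs of known per-source
  amplitude riding on low-frequency baseline drift and broadband noise,
  with occasional postsynaptic escape-spike artifacts;
* "self-target" animal profiles obtained by simulating a known parameter
  set and wrapping its measured metrics as targets, so parameter-recovery
  searches have a planted optimum with zero error.

All generators are pure functions of their specification (including its
seed): identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import (
    ConductanceParameterSet,
    apply_parameter_set,
    build_ensemble,
    set_synaptic_strengths,
)
from .engine import simulate
from .errors import GenerationError, LeechHeartError, SpecificationError
from .metrics import TargetProfile, compute_metric_vector
from .pattern import COORDINATIONS, PREMOTOR_UNITS, PremotorPattern
from .population import AnimalProfile
from .profiles import SynapticProfile
from .sta import VoltageClampRecording

__all__ = [
    "PatternSpec",
    "ClampSpec",
    "generate_premotor_pattern",
    "generate_voltage_clamp",
    "generate_target_profile",
]


@dataclass(frozen=True)
class PatternSpec:
    """Premotor pattern generator settings.

    Defaults describe a typical heartbeat rhythm: 6 s cycle period, burst
    duty cycle 0.55, 10 Hz intra-burst firing, a peristaltic premotor phase
    spread of 0.11 cycles (rear-to-front: HN(7) earliest, HN(3) latest) and
    a near-zero synchronous spread, with 10 ms spike-time jitter.
    """

    period: float = 6.0
    duty_cycle: float = 0.55
    intra_burst_rate: float = 10.0
    pm_delta_phi: float = 0.11  # peristaltic spread HN(3)-HN(7)
    sync_delta_phi: float = 0.02  # synchronous spread
    jitter_sd: float = 0.010  # s
    rate_cv: float = 0.05  # per-unit, per-cycle intra-burst rate variability
    #: fixed per-unit deviation of the mean intra-burst rate; distinct unit
    #: rates make cross-unit spike phases slip by >= one interspike interval
    #: per burst, as they do between recorded interneurons
    rate_spread: float = 0.05
    n_cycles: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.duty_cycle < 1:
            raise SpecificationError("duty cycle must lie in (0, 1)")
        if self.jitter_sd < 0 or self.rate_cv < 0 or self.rate_spread < 0:
            raise SpecificationError("jitter and rate variability must be >= 0")
        for dphi in (self.pm_delta_phi, self.sync_delta_phi):
            if not 0 <= dphi < 1:
                raise SpecificationError("phase spreads must lie in [0, 1)")
            if dphi + self.duty_cycle >= 1.0:
                raise SpecificationError(
                    f"requested spread {dphi} incompatible with duty cycle "
                    f"{self.duty_cycle}: bursts would wrap across cycles"
                )


def _unit_offsets(spread: float) -> dict:
    """Burst-median phase per unit: rear-to-front, HN(7) first, evenly spaced."""
    return {
        "HN7": 0.0,
        "HN6": spread / 3.0,
        "HN4": 2.0 * spread / 3.0,
        "HN3": spread,
    }


def generate_premotor_pattern(spec: PatternSpec) -> PremotorPattern:
    """Generate bursting trains for the four premotor interneurons.

    Each unit fires one burst per cycle (duty_cycle * period long at
    intra_burst_rate), centred so that its *median spike* realizes the
    requested phase offset — the burst median is the phase marker used
    throughout the analysis, so with zero jitter the measured spread equals
    the requested value exactly.  Every spike is jittered independently,
    and each unit's intra-burst rate differs systematically
    (``rate_spread``) and varies from cycle to cycle (``rate_cv``), as
    recorded interneurons' rates do — without this the four units would be
    artificially phase-locked to each other at the firing period.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.period
    n_spikes = max(2, int(np.floor(spec.duty_cycle * T * spec.intra_burst_rate)) + 1)
    base = np.arange(n_spikes) / spec.intra_burst_rate
    if n_spikes % 2:
        base_med = base[n_spikes // 2]
    else:
        base_med = 0.5 * (base[n_spikes // 2 - 1] + base[n_spikes // 2])
    # lead-in so jittered, median-centred bursts stay at positive times
    # (rate factors are floored at 0.7, so a burst extends at most
    # base_med / 0.7 before its median)
    lead = 0.2 + 3.0 * spec.jitter_sd + base_med * (1.0 / 0.7 - 1.0)

    trains = {}
    requested = {}
    for coord in COORDINATIONS:
        spread = spec.pm_delta_phi if coord == "peristaltic" else spec.sync_delta_phi
        requested[coord] = spread
        offsets = _unit_offsets(spread)
        unit_rate = {
            "HN3": 1.0 + spec.rate_spread,
            "HN4": 1.0 - 0.7 * spec.rate_spread,
            "HN6": 1.0 + 0.3 * spec.rate_spread,
            "HN7": 1.0 - spec.rate_spread,
        }
        for unit in PREMOTOR_UNITS:
            spikes = []
            for c in range(spec.n_cycles):
                center = lead + (c + offsets[unit]) * T + base_med
                factor = unit_rate[unit]
                if spec.rate_cv > 0:
                    factor *= 1.0 + spec.rate_cv * rng.standard_normal()
                factor = min(max(factor, 0.7), 1.5)
                s = center + (base - base_med) / factor
                if spec.jitter_sd > 0:
                    s = s + rng.normal(0.0, spec.jitter_sd, n_spikes)
                spikes.append(s)
            spikes = np.sort(np.concatenate(spikes))
            # enforce strict monotonicity after jitter
            eps = 1e-6
            for i in range(1, spikes.size):
                if spikes[i] <= spikes[i - 1]:
                    spikes[i] = spikes[i - 1] + eps
            trains[(unit, coord)] = spikes
    return PremotorPattern(trains, T, pm_delta_phi_spec=requested)


@dataclass(frozen=True)
class ClampSpec:
    """Voltage-clamp recording generator settings.

    ``amplitudes`` are the true per-source IPSC peak amplitudes in nA
    (positive: outward clamp current); each event's amplitude varies
    trial-to-trial by a lognormal factor of coefficient of variation
    ``amplitude_cv``.  The trace adds sinusoidal-plus-random-walk baseline
    drift, white noise (default SD = 25% of the largest amplitude) and
    escape-spike artifacts at Poisson times.
    """

    amplitudes: dict = field(
        default_factory=lambda: {"HN3": 0.1, "HN4": 0.2, "HN6": 0.4, "HN7": 0.3}
    )
    rise_tau: float = 0.0015  # s
    decay_tau: float = 0.012  # s
    amplitude_cv: float = 0.2
    drift_amplitude: float = 0.3  # nA
    drift_frequency: float = 0.1  # Hz
    noise_sd: float = 0.1  # nA
    escape_rate: float = 0.2  # Hz
    sampling_rate: float = 10000.0  # Hz
    #: "both" concatenates a peristaltic and a synchronous epoch in one
    #: trace, as recordings pooled across the two coordination modes are
    coordination: str = "both"
    seed: int = 0

    def __post_init__(self):
        if any(a < 0 for a in self.amplitudes.values()):
            raise SpecificationError("IPSC amplitudes must be >= 0")
        if self.sampling_rate < 6000.0:
            raise SpecificationError("sampling rate must be >= 6 kHz")


def _ipsc_kernel(rise, decay, fs):
    tp = rise * decay / (decay - rise) * np.log(decay / rise)
    t = np.arange(int(np.ceil(8 * decay * fs))) / fs
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / (np.exp(-tp / decay) - np.exp(-tp / rise))


def generate_voltage_clamp(spec: ClampSpec, pattern: PremotorPattern,
                           motor_neuron: str = "HE8"):
    """Synthesize a voltage-clamp recording driven by a premotor pattern.

    Returns ``(recording, truth)`` where ``truth`` holds the per-source
    amplitudes, the kernel time constants, the per-event amplitude factors
    and the escape-spike times actually planted.
    """
    fs = spec.sampling_rate
    if spec.coordination == "both":
        epoch = pattern.duration() + 1.0
        trains = {
            u: np.concatenate(
                [pattern.train(u, "peristaltic"),
                 pattern.train(u, "synchronous") + epoch]
            )
            for u in PREMOTOR_UNITS
        }
        duration = 2 * epoch + 0.5
    else:
        trains = {u: pattern.train(u, spec.coordination) for u in PREMOTOR_UNITS}
        duration = pattern.duration() + 0.5
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)
    kernel = _ipsc_kernel(spec.rise_tau, spec.decay_tau, fs)

    current = np.zeros(n)
    event_factors = {}
    lognorm_sd = np.sqrt(np.log(1.0 + spec.amplitude_cv**2))
    for unit in PREMOTOR_UNITS:
        amp = spec.amplitudes.get(unit, 0.0)
        spikes = trains[unit]
        factors = (
            rng.lognormal(-0.5 * lognorm_sd**2, lognorm_sd, spikes.size)
            if spec.amplitude_cv > 0
            else np.ones(spikes.size)
        )
        event_factors[unit] = factors
        for f, ts in zip(factors, spikes):
            i = int(round(ts * fs))
            if i >= n or i + kernel.size <= 0:
                continue
            j = max(-i, 0)
            m = min(kernel.size, n - i)
            current[i + j : i + m] += amp * f * kernel[j:m]

    # baseline drift: slow sinusoid plus a gentle random walk
    phase = rng.uniform(0, 2 * np.pi)
    current += spec.drift_amplitude * np.sin(
        2 * np.pi * spec.drift_frequency * t + phase
    )
    if spec.drift_amplitude > 0:
        walk = np.cumsum(rng.normal(0.0, spec.drift_amplitude / (2 * np.sqrt(n)), n))
        current += walk
    if spec.noise_sd > 0:
        current += rng.normal(0.0, spec.noise_sd, n)

    # postsynaptic escape spikes: large biphasic transients
    n_escape = rng.poisson(spec.escape_rate * duration)
    escape_times = np.sort(rng.uniform(0.05, duration - 0.05, n_escape))
    if n_escape:
        width = 0.0015
        for ts in escape_times:
            i0 = int((ts - 5 * width) * fs)
            i1 = int((ts + 5 * width) * fs)
            i0, i1 = max(i0, 0), min(i1, n)
            tt = t[i0:i1] - ts
            current[i0:i1] += 2.0 * (-tt / width) * np.exp(
                0.5 - 0.5 * (tt / width) ** 2
            )

    rec = VoltageClampRecording(
        current=current,
        rate=fs,
        presynaptic=trains,
        escape_spikes=escape_times,
        motor_neuron=motor_neuron,
    )
    truth = {
        "amplitudes": dict(spec.amplitudes),
        "rise_tau": spec.rise_tau,
        "decay_tau": spec.decay_tau,
        "event_factors": event_factors,
        "escape_times": escape_times,
    }
    return rec, truth


def generate_target_profile(
    params: ConductanceParameterSet,
    profile: SynapticProfile,
    pattern: PremotorPattern,
    config: dict = None,
    label: str = "synthetic",
    duration: float = None,
    step: float = 2e-4,
    metric_kwargs: dict = None,
) -> AnimalProfile:
    """Simulate a known model and wrap its metrics as an animal's targets.

    The generating parameter set evaluated against the returned profile has
    MAE = 0 by construction (a planted optimum for recovery searches).
    Target ranges are the standard per-metric ranges.
    """
    if duration is None:
        duration = 8 * pattern.period
    circuit = set_synaptic_strengths(
        apply_parameter_set(build_ensemble(config), params), profile
    )
    try:
        sim = simulate(circuit, pattern, duration=duration, step=step)
        mv = compute_metric_vector(sim, pattern, **(metric_kwargs or {}))
    except LeechHeartError as exc:
        raise GenerationError(
            f"parameter set produced degenerate activity: {exc}"
        ) from exc
    targets = TargetProfile.from_metric_vector(mv, animal=label)
    return AnimalProfile(label, pattern, profile, targets)
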