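"""Playback synaptic conductance waveforms with short-term depression.

The premotor interneurons inhibit the motor neurons through graded chemical
synapses; in the playback paradigm the presynaptic spike trains are known,
so each connection's conductance is a deterministic function of its spike
times: a sum of delayed double-exponential kernels, each scaled by a
single-factor depression state that decrements multiplicatively at every
spike and recovers exponentially between spikes.
"""

from __future__ import annotations

import math

import numpy as np

from .circuit import SynapseSpec
from .errors import InputError
from .pattern import MOTOR_SEGMENT, UNIT_SEGMENT

__all__ = [
    "kernel_peak_time",
    "depression_factors",
    "synaptic_conductance_waveform",
    "conduction_delay",
]


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the maximum of ``exp(-t/decay) - exp(-t/rise)``."""
    if not (0 < rise_tau < decay_tau):
        raise InputError("need 0 < rise_tau < decay_tau")
    return rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)


def depression_factors(spike_times, spec: SynapseSpec) -> np.ndarray:
    """Per-spike amplitude factors of the depression state.

    The state D starts at 1; each spike is scaled by the current D and then
    D is decremented multiplicatively by ``(1 - depression_increment)``;
    between spikes D recovers toward 1 as ``1 - (1-D) exp(-dt/tau_rec)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and np.any(np.diff(spike_times) <= 0):
        raise InputError("spike times must be strictly increasing")
    d = spec.depression_increment
    tau = spec.depression_recovery_tau
    out = np.empty(spike_times.size)
    state = 1.0
    last = None
    for i, t in enumerate(spike_times):
        if last is not None:
            state = 1.0 - (1.0 - state) * math.exp(-(t - last) / tau)
        out[i] = state
        state *= 1.0 - d
        last = t
    return out


def synaptic_conductance_waveform(
    spike_times,
    spec: SynapseSpec,
    t_grid,
    delay: float = 0.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Conductance time series (nS) of one connection on a uniform grid.

    Each spike contributes a delayed double-exponential kernel normalized to
    unit peak, so a single non-depressed spike peaks at
    ``scale * unitary_conductance``.  Successive spikes are scaled by the
    depression factors.  Spike times are snapped to the grid (the grid step
    is the integration step, well below the kernel rise time).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2:
        raise InputError("time grid must have at least 2 points")
    dt = t_grid[1] - t_grid[0]
    spike_times = np.asarray(spike_times, dtype=float)
    g = np.zeros(t_grid.size)
    if spike_times.size == 0:
        return g
    if np.any(np.diff(spike_times) <= 0):
        raise InputError("spike times must be strictly increasing")

    tr, td = spec.rise_tau, spec.decay_tau
    tp = kernel_peak_time(tr, td)
    norm = math.exp(-tp / td) - math.exp(-tp / tr)
    klen = int(math.ceil(8.0 * td / dt))
    kt = np.arange(klen) * dt
    kernel = (np.exp(-kt / td) - np.exp(-kt / tr)) / norm

    amp = spec.unitary_conductance * scale * depression_factors(spike_times, spec)
    t0 = t_grid[0]
    n = t_grid.size
    for a, ts in zip(amp, spike_times + delay):
        i = int(round((ts - t0) / dt))
        if i >= n:
            continue
        if i < 0:
            # spike (after delay) before the grid: add the kernel tail
            j = -i
            if j >= klen:
                continue
            m = min(klen - j, n)
            g[:m] += a * kernel[j : j + m]
        else:
            m = min(klen, n - i)
            g[i : i + m] += a * kernel[:m]
    return g


def conduction_delay(unit: str, motor_neuron: str, spec: SynapseSpec) -> float:
    """Conduction delay from a premotor interneuron to a motor neuron:
    a fixed delay per segment of separation between their ganglia."""
    return spec.delay_per_segment * abs(
        MOTOR_SEGMENT[motor_neuron] - UNIT_SEGMENT[unit]
    )
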