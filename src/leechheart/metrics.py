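"""Burst characteristics and optimization metrics for heartbeat motor output.

The functional output of the leech heartbeat motor circuit is quantified by a
small set of per-burst characteristics extracted from membrane-potential
traces (or directly from spike trains): duty cycle, within-burst spike
frequency, slow-wave envelope height, spike height, burst-median phase, and
the motor phase progression mdphi (the phase difference from motor neuron
HE(8) to HE(12)).  For one bilateral ensemble simulation this yields exactly
18 optimized metrics: 4 per-neuron metrics x 2 motor neurons x 2
coordinations, plus one phase progression per coordination.  Absolute
burst-median phases are reported as auxiliary values but are not optimized.

Metrics are scored against a target profile by range-normalized errors,
``(metric - target) / range``; the maximal absolute error over all metrics
(MAE) summarises a model, and MAE < 1 (strictly) defines a "good" model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    InputError,
    InsufficientActivityError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "Burst",
    "BurstSequence",
    "MetricVector",
    "TargetProfile",
    "MetricErrorVector",
    "METRIC_NAMES",
    "TABLE_RANGES",
    "detect_spikes",
    "segment_bursts",
    "slow_wave",
    "slow_wave_height",
    "phase_of_trains",
    "wrap_phase",
    "circular_mean_phase",
    "compute_metric_vector",
    "metric_errors",
]

#: Per-metric target ranges used for range-normalizing errors.  Duty cycle and
#: phases are in cycle fractions, spike frequency in Hz, heights in mV.
TABLE_RANGES = {
    "duty_cycle": 0.10,
    "spike_frequency": 7.0,
    "slow_wave_height": 5.0,
    "spike_height": 7.5,
    "m_delta_phi": 0.06,
    "phase": 0.03,
}

MOTOR_NEURONS = ("HE8", "HE12")
COORDINATIONS = ("peristaltic", "synchronous")

#: Fixed order of the 18 optimized metric names.
METRIC_NAMES = tuple(
    f"{neuron}.{coord}.{metric}"
    for coord in COORDINATIONS
    for neuron in MOTOR_NEURONS
    for metric in ("duty_cycle", "spike_frequency", "slow_wave_height", "spike_height")
) + tuple(f"{coord}.m_delta_phi" for coord in COORDINATIONS)


def wrap_phase(x: float) -> float:
    """Wrap a phase difference into the half-open interval (-0.5, 0.5]."""
    w = x % 1.0
    if w > 0.5:
        w -= 1.0
    return w


def circular_mean_phase(phases) -> float:
    """Circular mean of phases given in cycle fractions, returned in [0, 1)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise InputError("circular mean of an empty phase set")
    z = np.exp(2j * np.pi * phases).mean()
    if abs(z) < 1e-12:
        raise InputError("circular mean undefined: phases are balanced")
    return float(np.angle(z) / (2 * np.pi) % 1.0)


# ---------------------------------------------------------------------------
# spike and burst extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Burst:
    """One burst of spikes: its first/last/median spike and summary stats."""

    first: float
    last: float
    median: float
    n_spikes: int
    spike_rate: float  # Hz, (n-1)/(last-first)
    mean_height: float = float("nan")  # mV, NaN when heights were not supplied

    @property
    def duration(self) -> float:
        return self.last - self.first


@dataclass
class BurstSequence:
    """Time-ordered, non-overlapping bursts extracted from one spike train."""

    bursts: list

    def __len__(self):
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    def __getitem__(self, i):
        return self.bursts[i]

    @property
    def median_times(self) -> np.ndarray:
        return np.array([b.median for b in self.bursts])

    def after(self, t0: float) -> "BurstSequence":
        """Bursts whose median spike falls at or after ``t0`` (transient discard)."""
        return BurstSequence([b for b in self.bursts if b.median >= t0])


def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if dt.size == 0:
        raise InputError("trace must contain at least two samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise InputError("trace is not uniformly sampled")
    return float(dt[0])


def slow_wave(voltage, fs: float, cutoff: float = 2.0, order: int = 4):
    """Zero-phase low-pass filtered trace (the slow-wave envelope).

    A Butterworth filter of half the requested order is applied forward and
    backward (``sosfiltfilt``), giving a zero-phase response of effective
    order ``order``.
    """
    voltage = np.asarray(voltage, dtype=float)
    if cutoff >= fs / 2:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    if order < 2 or order % 2:
        raise ParameterError("filter order must be an even integer >= 2")
    sos = signal.butter(order // 2, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, voltage)


def detect_spikes(
    voltage,
    fs: float = None,
    times=None,
    threshold: float = -20.0,
    baseline_cutoff: float = 2.0,
):
    """Detect spikes as upward threshold crossings of a uniformly sampled trace.

    Returns ``(spike_times, spike_heights)``.  Each upward crossing of
    ``threshold`` yields one event placed at the local voltage maximum before
    the trace falls back below threshold.  The height is the peak voltage
    minus the slow-wave baseline (low-pass envelope) at the peak time.

    One of ``fs`` or ``times`` must be given; ``times`` must be uniform.
    """
    voltage = np.asarray(voltage, dtype=float)
    if times is not None:
        times = np.asarray(times, dtype=float)
        dt = _check_uniform(times)
        fs = 1.0 / dt
        t0 = times[0]
    elif fs is not None:
        t0 = 0.0
    else:
        raise InputError("either fs or times is required")

    above = voltage >= threshold
    # upward crossings: below at i-1, at/above at i
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if up.size == 0:
        return np.empty(0), np.empty(0)

    try:
        base = slow_wave(voltage, fs, cutoff=baseline_cutoff)
    except ParameterError:
        raise
    except ValueError:
        # trace too short for stable filtering: flat baseline
        base = np.full_like(voltage, float(np.median(voltage)))

    spike_times = []
    heights = []
    n = voltage.size
    for i in up:
        j = i
        while j < n and above[j]:
            j += 1
        seg = voltage[i:j]
        k = i + int(np.argmax(seg))
        spike_times.append(t0 + k / fs)
        heights.append(voltage[k] - base[k])
    return np.asarray(spike_times), np.asarray(heights)


def segment_bursts(
    spike_times,
    max_isi: float = 1.0,
    min_spikes: int = 4,
    heights=None,
) -> BurstSequence:
    """Partition a sorted spike train into bursts.

    A burst is a maximal run of spikes whose consecutive inter-spike
    intervals are all <= ``max_isi``; runs with fewer than ``min_spikes``
    spikes are discarded.  The median spike is the middle spike by index
    (mean of the two middle spike times for even counts).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and np.any(np.diff(spike_times) < 0):
        raise InputError("spike times must be sorted")
    if heights is not None:
        heights = np.asarray(heights, dtype=float)
        if heights.shape != spike_times.shape:
            raise InputError("heights must align with spike times")

    bursts = []
    if spike_times.size == 0:
        return BurstSequence(bursts)

    breaks = np.flatnonzero(np.diff(spike_times) > max_isi)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [spike_times.size]))
    for a, b in zip(starts, stops):
        n = b - a
        if n < min_spikes:
            continue
        run = spike_times[a:b]
        if n % 2:
            med = run[n // 2]
        else:
            med = 0.5 * (run[n // 2 - 1] + run[n // 2])
        rate = (n - 1) / (run[-1] - run[0]) if n > 1 and run[-1] > run[0] else 0.0
        mh = float(np.mean(heights[a:b])) if heights is not None else float("nan")
        bursts.append(Burst(run[0], run[-1], float(med), int(n), float(rate), mh))
    return BurstSequence(bursts)


def slow_wave_height(
    voltage,
    fs: float,
    cutoff: float = 2.0,
    cycle_bounds_s=None,
) -> float:
    """Cycle-averaged peak-to-trough height of the slow-wave envelope (mV).

    ``cycle_bounds_s``: optional sequence of (start, end) times delimiting
    cycles; when omitted the whole trace is treated as one cycle.
    """
    filt = slow_wave(voltage, fs, cutoff=cutoff)
    if cycle_bounds_s is None:
        return float(filt.max() - filt.min())
    heights = []
    for a, b in cycle_bounds_s:
        ia, ib = int(round(a * fs)), int(round(b * fs))
        ia, ib = max(ia, 0), min(ib, filt.size)
        if ib - ia < 2:
            continue
        seg = filt[ia:ib]
        heights.append(seg.max() - seg.min())
    if not heights:
        raise InputError("no complete cycle inside the trace")
    return float(np.mean(heights))


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------

def _phase_to_reference(burst_medians, ref_medians, period: float) -> float:
    """Mean phase of burst medians relative to the preceding reference median.

    phi_b = ((median_b - ref_prev) / period) mod 1 with ref_prev the latest
    reference median at or before median_b; the per-burst phases are combined
    by a circular mean.
    """
    ref = np.asarray(ref_medians, dtype=float)
    phases = []
    for t in np.asarray(burst_medians, dtype=float):
        prev = ref[ref <= t]
        if prev.size == 0:
            continue
        phases.append(((t - prev[-1]) / period) % 1.0)
    if not phases:
        raise InsufficientActivityError("no burst has a preceding reference burst")
    return circular_mean_phase(phases)


def phase_of_trains(
    he8_medians,
    he12_medians,
    ref_medians,
    period: float,
):
    """Phases of HE(8)/HE(12) burst medians and their progression mdphi.

    Returns ``(phi_he8, phi_he12, m_delta_phi)`` with phases in [0, 1)
    relative to the reference burst medians and the motor phase progression
    wrapped into (-0.5, 0.5], computed as the phase difference from HE(8)
    to HE(12).
    """
    p8 = _phase_to_reference(he8_medians, ref_medians, period)
    p12 = _phase_to_reference(he12_medians, ref_medians, period)
    return p8, p12, wrap_phase(p8 - p12)


# ---------------------------------------------------------------------------
# the 18-entry metric vector
# ---------------------------------------------------------------------------

@dataclass
class MetricVector:
    """The optimized metrics of one ensemble simulation plus auxiliary phases.

    ``values`` holds exactly the 18 optimized entries keyed by
    ``"<neuron>.<coordination>.<metric>"`` / ``"<coordination>.m_delta_phi"``;
    ``phases`` holds the auxiliary absolute burst-median phases, which are
    reported but never optimized.
    """

    values: dict
    phases: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [k for k in METRIC_NAMES if k not in self.values]
        extra = [k for k in self.values if k not in METRIC_NAMES]
        if missing or extra:
            raise ValidationError(
                f"metric vector must have exactly the 18 optimized entries; "
                f"missing={missing}, extra={extra}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in METRIC_NAMES])

    def __len__(self):
        return len(self.values)


@dataclass
class TargetProfile:
    """Per-metric target values and target ranges for one animal."""

    targets: dict
    ranges: dict
    animal: str = "synthetic"

    def __post_init__(self):
        for k, r in self.ranges.items():
            if not r > 0:
                raise ValidationError(f"target range for {k} must be > 0, got {r}")

    @classmethod
    def from_metric_vector(cls, metrics: "MetricVector", animal: str = "synthetic"):
        """Wrap measured metrics as targets with the standard target ranges."""
        ranges = {k: TABLE_RANGES[k.rsplit(".", 1)[1]] for k in METRIC_NAMES}
        return cls(dict(metrics.values), ranges, animal)

    def to_dict(self) -> dict:
        return {
            "animal": self.animal,
            "metrics": {
                k: {"target": self.targets[k], "range": self.ranges[k]}
                for k in self.targets
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetProfile":
        targets = {k: v["target"] for k, v in d["metrics"].items()}
        ranges = {k: v["range"] for k, v in d["metrics"].items()}
        return cls(targets, ranges, d.get("animal", "synthetic"))


@dataclass
class MetricErrorVector:
    """Range-normalized metric errors, their MAE, and the accept flag."""

    errors: dict
    mae: float
    is_good: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.errors[k] for k in METRIC_NAMES])


def metric_errors(metrics: MetricVector, targets: TargetProfile) -> MetricErrorVector:
    """Score metrics against a target profile.

    Each error is ``(metric - target) / range``; MAE is the maximum absolute
    normalized error, and a model is good iff MAE < 1 (strict).
    """
    errors = {}
    for k, v in metrics.values.items():
        if k not in targets.targets or k not in targets.ranges:
            raise InputError(f"target profile is missing metric {k!r}")
        errors[k] = (v - targets.targets[k]) / targets.ranges[k]
    mae = max(abs(e) for e in errors.values())
    return MetricErrorVector(errors, float(mae), bool(mae < 1.0))


def compute_metric_vector(
    sim,
    pattern,
    reference_unit: str = "HN4",
    threshold: float = -20.0,
    max_isi: float = 1.0,
    min_spikes: int = 4,
    transient_cycles: int = 2,
    min_bursts: int = 3,
    slow_wave_cutoff: float = 2.0,
) -> MetricVector:
    """Extract the 18 optimized metrics from one bilateral ensemble simulation.

    ``sim`` is a :class:`~leechheart.engine.SimulationResult`; ``pattern`` is
    the premotor pattern that drove it.  Phase 0 of each coordination is the
    burst median of the ipsilateral reference interneuron (HN(4) by default).
    The first ``transient_cycles`` input cycles are discarded before any
    metric is computed; at least ``min_bursts`` bursts per neuron must remain.
    """
    period = pattern.period
    t_discard = sim.t[0] + transient_cycles * period
    fs = 1.0 / (sim.t[1] - sim.t[0])
    values = {}
    phases = {}

    for side, coord in sim.assignment.items():
        ref_bursts = segment_bursts(
            pattern.train(reference_unit, coord), max_isi=max_isi, min_spikes=min_spikes
        )
        ref_medians = ref_bursts.median_times
        if ref_medians.size < 2:
            raise InsufficientActivityError("reference train has fewer than 2 bursts")
        cyc_refs = ref_medians[ref_medians >= t_discard - period]
        cycle_bounds = list(zip(cyc_refs[:-1] - sim.t[0], cyc_refs[1:] - sim.t[0]))

        medians = {}
        for neuron in MOTOR_NEURONS:
            v = sim.soma_voltage(side, neuron)
            st, hh = detect_spikes(v, fs=fs, threshold=threshold)
            st = st + sim.t[0]
            bursts = segment_bursts(
                st, max_isi=max_isi, min_spikes=min_spikes, heights=hh
            ).after(t_discard)
            if len(bursts) < min_bursts:
                raise InsufficientActivityError(
                    f"{neuron} ({side}/{coord}): {len(bursts)} bursts "
                    f"after transient discard, need >= {min_bursts}"
                )
            medians[neuron] = bursts.median_times
            key = f"{neuron}.{coord}"
            values[f"{key}.duty_cycle"] = float(
                np.mean([b.duration for b in bursts]) / period
            )
            values[f"{key}.spike_frequency"] = float(
                np.mean([b.spike_rate for b in bursts])
            )
            values[f"{key}.spike_height"] = float(
                np.mean([b.mean_height for b in bursts])
            )
            values[f"{key}.slow_wave_height"] = slow_wave_height(
                v, fs, cutoff=slow_wave_cutoff, cycle_bounds_s=cycle_bounds
            )

        p8, p12, mdphi = phase_of_trains(
            medians["HE8"], medians["HE12"], ref_medians, period
        )
        phases[f"HE8.{coord}.phase"] = p8
        phases[f"HE12.{coord}.phase"] = p12
        values[f"{coord}.m_delta_phi"] = mdphi

    return MetricVector(values, phases)
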