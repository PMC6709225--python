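"""Spike-triggered averaging of inhibitory postsynaptic currents.

Synaptic strength of each premotor-to-motor connection is estimated from
voltage-clamp current recordings of a motor neuron while the presynaptic
interneuron's spike times are known.  The estimator:

1. removes low-frequency current offsets with a zero-phase band-pass filter
   (5-3000 Hz by default) instead of re-zeroing each sweep at its trigger
   value, which is biased by coincident IPSCs from other inputs;
2. trims a fixed number of leading and trailing spikes from each
   presynaptic burst (the first and last IPSCs of a burst ride on strong
   facilitation/decay transients);
3. excludes sweeps whose window comes near a postsynaptic escape spike
   (spikes that escape the somatic voltage clamp due to poor space clamp);
4. averages the remaining trigger-aligned windows, reports the across-sweep
   SD envelope, and measures the amplitude from the local pre-peak baseline
   to the largest peak of IPSC polarity, with the trigger-to-peak latency.

Because premotor neurons fire quasi-tonically within bursts, the average
often shows multiple periodic peaks; the largest one is measured.
Per-animal strengths are reported relative to the largest input of each
motor neuron (max = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InputError, InsufficientDataError, ParameterError
from .metrics import segment_bursts
from .profiles import SynapticProfile

__all__ = [
    "VoltageClampRecording",
    "SweepSet",
    "STAResult",
    "align_offsets",
    "select_sweeps",
    "average_and_measure",
    "relative_weights",
    "estimate_profile",
]


@dataclass
class VoltageClampRecording:
    """A voltage-clamp current trace with its spike-time annotations.

    ``current`` is in nA at sampling rate ``rate`` (>= 6 kHz so the 3000 Hz
    band edge of the offset-alignment filter is below Nyquist);
    ``presynaptic`` maps each source interneuron to its spike times;
    ``escape_spikes`` are postsynaptic spikes that escaped the clamp.
    """

    current: np.ndarray
    rate: float
    presynaptic: dict
    escape_spikes: np.ndarray = None
    motor_neuron: str = "HE8"

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        if self.rate < 6000.0:
            raise InputError(f"sampling rate {self.rate} Hz < 6 kHz minimum")
        span = self.duration
        for unit, t in self.presynaptic.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > span):
                raise InputError(f"{unit} spike annotations outside the trace span")
            self.presynaptic[unit] = t
        if self.escape_spikes is None:
            self.escape_spikes = np.empty(0)
        self.escape_spikes = np.asarray(self.escape_spikes, dtype=float)

    @property
    def duration(self) -> float:
        return self.current.size / self.rate


def align_offsets(trace, rate: float, band=(5.0, 3000.0)):
    """Zero-phase band-pass filter removing low-frequency current offsets.

    After filtering, the mean over any multi-second window is ~0 while
    IPSC-band components (tens to hundreds of Hz) pass with <5% attenuation.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < low < high, got {band}")
    if hi >= rate / 2:
        raise ParameterError(f"high edge {hi} Hz >= Nyquist {rate / 2} Hz")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


@dataclass
class SweepSet:
    """Trigger-aligned current windows cut from the offset-aligned trace."""

    sweeps: np.ndarray  # (n_sweeps, n_lags)
    lags: np.ndarray  # s, relative to the trigger
    trigger_times: np.ndarray
    n_excluded_escape: int  # dropped near a postsynaptic escape spike
    n_excluded_bounds: int  # window exceeded the trace bounds

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_escape + self.n_excluded_bounds

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


def select_sweeps(
    rec: VoltageClampRecording,
    source: str,
    window=(-0.02, 0.08),
    n_trim=(2, 2),
    exclusion_radius: float = 0.010,
    aligned=None,
    burst_max_isi: float = 1.0,
    burst_min_spikes: int = 4,
) -> SweepSet:
    """Select and cut the usable trigger windows for one source interneuron.

    Per presynaptic burst the first ``n_trim[0]`` and last ``n_trim[1]``
    spikes are dropped; a sweep is excluded when its window comes within
    ``exclusion_radius`` of a postsynaptic escape spike, or when it exceeds
    the trace bounds (silently dropped but counted as excluded).
    """
    w0, w1 = window
    if not w0 < 0 < w1:
        raise ParameterError("window must cover the trigger (w0 < 0 < w1)")
    if aligned is None:
        aligned = align_offsets(rec.current, rec.rate)
    if source not in rec.presynaptic:
        raise InputError(f"no presynaptic spike train for {source!r}")

    lead, trail = n_trim
    triggers = []
    for burst in segment_bursts(
        rec.presynaptic[source], max_isi=burst_max_isi, min_spikes=burst_min_spikes
    ):
        spikes = rec.presynaptic[source]
        in_burst = spikes[(spikes >= burst.first) & (spikes <= burst.last)]
        kept = in_burst[lead : len(in_burst) - trail if trail else None]
        triggers.extend(kept)

    i0 = int(round(w0 * rec.rate))
    i1 = int(round(w1 * rec.rate))
    lags = np.arange(i0, i1) / rec.rate
    esc = rec.escape_spikes
    sweeps, used = [], []
    n_escape = n_bounds = 0
    for t in triggers:
        if esc.size and np.any(
            (esc >= t + w0 - exclusion_radius) & (esc <= t + w1 + exclusion_radius)
        ):
            n_escape += 1
            continue
        k = int(round(t * rec.rate))
        if k + i0 < 0 or k + i1 > aligned.size:
            n_bounds += 1
            continue
        sweeps.append(aligned[k + i0 : k + i1])
        used.append(t)
    sweeps = np.asarray(sweeps) if sweeps else np.empty((0, lags.size))
    return SweepSet(sweeps, lags, np.asarray(used), n_escape, n_bounds)


@dataclass
class STAResult:
    """Averaged sweep with its amplitude/latency measurement."""

    mean: np.ndarray  # nA vs lag
    sd: np.ndarray  # across-sweep SD envelope
    lags: np.ndarray  # s
    amplitude: float  # nA, local pre-peak baseline to largest peak
    latency: float  # s, trigger to peak
    n_used: int
    n_excluded: int


def average_and_measure(
    sweepset: SweepSet,
    search_interval=(0.002, 0.040),
    min_sweeps: int = 5,
    smoothing: float = 0.0005,
) -> STAResult:
    """Point-wise average the sweeps and measure the largest IPSC peak.

    Peaks are searched on the mean within ``search_interval`` after the
    trigger; the largest peak of outward (positive) polarity is selected.
    The amplitude is measured from the local pre-peak baseline (a short
    average around the trough between the trigger and the peak) to the
    peak.  The mean is lightly smoothed (``smoothing`` seconds, well below
    the IPSC width) before measurement; picking the largest value of an
    unsmoothed noisy average would bias weak amplitudes upward.
    """
    if sweepset.n_sweeps < min_sweeps:
        raise InsufficientDataError(
            f"{sweepset.n_sweeps} sweeps < minimum {min_sweeps}"
        )
    mean = sweepset.sweeps.mean(axis=0)
    sd = sweepset.sweeps.std(axis=0, ddof=1)
    lags = sweepset.lags
    if smoothing > 0:
        w = max(1, int(round(smoothing / (lags[1] - lags[0]))))
        if w > 1:
            mean = np.convolve(mean, np.ones(w) / w, mode="same")

    mask = (lags >= search_interval[0]) & (lags <= search_interval[1])
    idx = np.flatnonzero(mask)
    seg = mean[idx]
    peaks, _ = signal.find_peaks(seg)
    if peaks.size:
        best = idx[peaks[np.argmax(seg[peaks])]]
    else:
        best = idx[int(np.argmax(seg))]

    # local pre-peak baseline: a short average around the trough between
    # the trigger and the peak (a pointwise minimum would be noise-biased)
    zero = int(np.searchsorted(lags, 0.0))
    if best > zero:
        rel = int(np.argmin(mean[zero : best + 1]))
        tmin = zero + rel
        back = max(1, int(round(0.0015 / (lags[1] - lags[0]))))
        base = float(mean[max(tmin - back, 0) : tmin + 1].mean())
    else:
        base = float(mean[best])
    amplitude = float(mean[best] - base)
    return STAResult(
        mean=mean,
        sd=sd,
        lags=lags,
        amplitude=max(amplitude, 0.0),
        latency=float(lags[best]),
        n_used=sweepset.n_sweeps,
        n_excluded=sweepset.n_excluded,
    )


def relative_weights(amplitudes: dict, sds: dict = None) -> SynapticProfile:
    """Normalize measured per-connection amplitudes per motor neuron so the
    largest input has relative strength 1; SDs are scaled identically."""
    return SynapticProfile.from_amplitudes(amplitudes, sds)


def estimate_profile(
    recordings: dict,
    window=(-0.02, 0.08),
    n_trim=(2, 2),
    exclusion_radius: float = 0.010,
    search_interval=(0.002, 0.040),
) -> tuple:
    """Full STA pipeline over per-motor-neuron recordings.

    ``recordings`` maps motor neuron labels ("HE8", "HE12") to
    :class:`VoltageClampRecording`.  Returns ``(profile, results)`` with the
    normalized :class:`SynapticProfile` and the per-connection
    :class:`STAResult` objects keyed by ``(unit, motor_neuron)``.  A full
    profile needs both motor neurons; with recordings for only one of them
    the profile is ``None`` and only the measurements are returned.
    """
    amplitudes, sds, results = {}, {}, {}
    for he, rec in recordings.items():
        aligned = align_offsets(rec.current, rec.rate)
        for unit in rec.presynaptic:
            sel = select_sweeps(
                rec, unit, window=window, n_trim=n_trim,
                exclusion_radius=exclusion_radius, aligned=aligned,
            )
            res = average_and_measure(sel, search_interval=search_interval)
            results[(unit, he)] = res
            amplitudes[(unit, he)] = res.amplitude
            # within-animal variability of the amplitude estimate
            sds[(unit, he)] = float(
                np.interp(res.latency, sel.lags, res.sd) / np.sqrt(res.n_used)
            )
    if {"HE8", "HE12"} <= set(recordings):
        return relative_weights(amplitudes, sds), results
    return None, results


def sta_report(results: dict) -> pd.DataFrame:
    """Tabular per-connection STA report (amplitude, latency, counts)."""
    rows = []
    for (unit, he), r in sorted(results.items()):
        rows.append(
            dict(
                unit=unit,
                target=he,
                amplitude_nA=r.amplitude,
                latency_s=r.latency,
                n_used=r.n_used,
                n_excluded=r.n_excluded,
            )
        )
    return pd.DataFrame(rows)
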