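"""Spike-triggered averaging: alignment, sweep selection, measurement."""

import numpy as np
import pytest

import leechheart as lh
from leechheart.errors import InputError, InsufficientDataError, ParameterError
from leechheart.profiles import SynapticProfile
from leechheart.sta import (
    SweepSet,
    VoltageClampRecording,
    align_offsets,
    average_and_measure,
    relative_weights,
    select_sweeps,
)

FS = 10000.0


class TestAlignOffsets:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        trace = 0.5 + 0.05 * rng.standard_normal(int(10 * FS))
        out = align_offsets(trace, FS)
        assert abs(out.mean()) < 0.01

    def test_slow_drift_suppressed(self):
        t = np.arange(0, 30, 1 / FS)
        drift = 1.0 * np.sin(2 * np.pi * 0.1 * t)
        out = align_offsets(drift, FS)
        # residual drift < 5% of the original amplitude
        assert np.abs(out[int(2 * FS):-int(2 * FS)]).max() < 0.05

    def test_in_band_component_passes(self):
        t = np.arange(0, 10, 1 / FS)
        sig = np.sin(2 * np.pi * 50 * t)
        out = align_offsets(sig, FS)
        mid = out[int(2 * FS):-int(2 * FS)]
        assert mid.max() == pytest.approx(1.0, rel=0.05)

    def test_band_edge_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            align_offsets(np.zeros(1000), 5000.0, band=(5.0, 3000.0))


def _recording(n_bursts=5, spikes_per_burst=10, escape=(), duration=40.0):
    spikes = []
    for b in range(n_bursts):
        spikes.extend(5.0 * b + 1.0 + 0.1 * np.arange(spikes_per_burst))
    return VoltageClampRecording(
        current=np.zeros(int(duration * FS)),
        rate=FS,
        presynaptic={"HN4": np.array(spikes)},
        escape_spikes=np.array(escape),
    )


class TestSelectSweeps:
    def test_trimming_counts(self):
        rec = _recording(n_bursts=1, spikes_per_burst=10)
        sel = select_sweeps(rec, "HN4", n_trim=(2, 2))
        assert sel.n_sweeps == 6

    def test_five_bursts_of_eight_usable_spikes(self):
        rec = _recording(n_bursts=5, spikes_per_burst=12)
        sel = select_sweeps(rec, "HN4", n_trim=(2, 2))
        assert sel.n_sweeps == 40

    def test_escape_spike_excludes_sweep(self):
        rec = _recording(n_bursts=1, spikes_per_burst=10, escape=[1.45])
        sel = select_sweeps(rec, "HN4", n_trim=(2, 2), exclusion_radius=0.01,
                            window=(-0.02, 0.08))
        rec0 = _recording(n_bursts=1, spikes_per_burst=10)
        sel0 = select_sweeps(rec0, "HN4", n_trim=(2, 2))
        assert sel.n_excluded_escape >= 1
        assert sel.n_sweeps < sel0.n_sweeps

    def test_out_of_bounds_window_counted_not_raised(self):
        rec = _recording(n_bursts=1, spikes_per_burst=10, duration=1.9)
        sel = select_sweeps(rec, "HN4", n_trim=(0, 0), window=(-0.02, 0.08))
        assert sel.n_excluded_bounds >= 1
        assert sel.n_sweeps + sel.n_excluded == 10

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError):
            select_sweeps(_recording(), "HN9")


def _kernel_sweeps(amplitude=0.2, n=40, noise_sd=0.0, seed=0, second=None):
    lags = np.arange(-0.02, 0.08, 1 / FS)
    k = np.zeros_like(lags)
    m = lags >= 0.003
    k[m] = amplitude * np.exp(-(lags[m] - 0.003) / 0.01) * (
        1 - np.exp(-(lags[m] - 0.003) / 0.0015)
    ) / 0.65
    k *= amplitude / k.max()
    if second is not None:
        amp2, lat2 = second
        m2 = lags >= lat2
        k2 = np.zeros_like(lags)
        k2[m2] = np.exp(-(lags[m2] - lat2) / 0.01) * (
            1 - np.exp(-(lags[m2] - lat2) / 0.0015)
        )
        k = k + amp2 * k2 / k2.max()
    rng = np.random.default_rng(seed)
    sweeps = np.tile(k, (n, 1))
    if noise_sd:
        sweeps = sweeps + rng.normal(0, noise_sd, sweeps.shape)
    return SweepSet(sweeps, lags, np.zeros(n), 0, 0)


class TestAverageAndMeasure:
    def test_noiseless_amplitude_recovered(self):
        res = average_and_measure(_kernel_sweeps(amplitude=0.2))
        assert res.amplitude == pytest.approx(0.2, rel=0.01)
        assert 0.002 < res.latency < 0.02

    def test_noisy_amplitude_within_ten_percent(self):
        res = average_and_measure(_kernel_sweeps(amplitude=0.2, noise_sd=0.05, n=40))
        assert res.amplitude == pytest.approx(0.2, rel=0.10)

    def test_largest_peak_selected(self):
        """With two peaks (0.15 then 0.2 nA) the larger, later one is the
        one measured — its latency is reported, and the amplitude is that
        peak's (riding slightly on the first peak's decay)."""
        res = average_and_measure(
            _kernel_sweeps(amplitude=0.15, second=(0.2, 0.025))
        )
        assert res.latency == pytest.approx(0.028, abs=0.005)
        assert res.amplitude == pytest.approx(0.2, rel=0.15)
        assert res.amplitude > 0.15

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(InsufficientDataError):
            average_and_measure(_kernel_sweeps(n=4))

    def test_doubling_sweeps_does_not_raise_sd_envelope(self):
        """Across seeds, the mean SD envelope with 2n sweeps is (on average)
        no larger than with n sweeps."""
        deltas = []
        for seed in range(8):
            a = average_and_measure(_kernel_sweeps(noise_sd=0.05, n=20, seed=seed))
            b = average_and_measure(_kernel_sweeps(noise_sd=0.05, n=40, seed=seed))
            deltas.append(b.sd.mean() - a.sd.mean())
        assert np.mean(deltas) < 0.005


class TestRelativeWeights:
    def test_normalization_by_largest_input(self):
        amps = {("HN3", "HE8"): 0.1, ("HN4", "HE8"): 0.2,
                ("HN6", "HE8"): 0.4, ("HN7", "HE8"): 0.3,
                ("HN3", "HE12"): 0.1, ("HN4", "HE12"): 0.1,
                ("HN6", "HE12"): 0.1, ("HN7", "HE12"): 0.1}
        prof = relative_weights(amps)
        assert prof.w[("HN3", "HE8")] == pytest.approx(0.25)
        assert prof.w[("HN4", "HE8")] == pytest.approx(0.5)
        assert prof.w[("HN6", "HE8")] == pytest.approx(1.0)
        assert prof.w[("HN7", "HE8")] == pytest.approx(0.75)
        # equal amplitudes -> all weights 1
        assert all(prof.w[(u, "HE12")] == 1.0 for u in ("HN3", "HN4", "HN6", "HN7"))

    def test_all_zero_amplitudes_rejected(self):
        amps = {(u, he): 0.0 for u in ("HN3", "HN4", "HN6", "HN7")
                for he in ("HE8", "HE12")}
        with pytest.raises(lh.LeechHeartError):
            relative_weights(amps)

    def test_sd_scaled_by_same_factor(self):
        amps = {(u, "HE8"): a for u, a in
                zip(("HN3", "HN4", "HN6", "HN7"), (0.1, 0.2, 0.4, 0.3))}
        amps.update({(u, "HE12"): 0.2 for u in ("HN3", "HN4", "HN6", "HN7")})
        sds = {k: 0.04 for k in amps}
        prof = relative_weights(amps, sds)
        assert prof.sd[("HN3", "HE8")] == pytest.approx(0.1)
        assert prof.sd[("HN3", "HE12")] == pytest.approx(0.2)


def test_low_sampling_rate_rejected():
    with pytest.raises(InputError):
        VoltageClampRecording(np.zeros(1000), 4000.0, {})


def test_annotations_outside_span_rejected():
    with pytest.raises(InputError):
        VoltageClampRecording(np.zeros(1000), FS, {"HN4": np.array([5.0])})
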