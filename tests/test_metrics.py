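"""Burst metrics, slow-wave extraction and range-normalized scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leechheart as lh
from leechheart.errors import InputError, ParameterError
from leechheart.metrics import (
    METRIC_NAMES,
    TABLE_RANGES,
    MetricVector,
    TargetProfile,
    detect_spikes,
    metric_errors,
    phase_of_trains,
    segment_bursts,
    slow_wave_height,
    wrap_phase,
)


class TestDetectSpikes:
    def test_flat_trace_yields_no_events(self):
        t, h = detect_spikes(np.full(5000, -50.0), fs=1000.0)
        assert t.size == 0 and h.size == 0

    def test_threshold_above_all_peaks_yields_no_events(self):
        v = -50 + 5 * np.sin(np.linspace(0, 20 * np.pi, 5000))
        t, _ = detect_spikes(v, fs=1000.0, threshold=-20.0)
        assert t.size == 0

    def test_synthetic_spikes_recovered_with_heights(self):
        """10 planted 15 mV spikes on a slow baseline: 10 events with
        heights 15 +- 0.5 mV."""
        fs = 2000.0
        t = np.arange(0, 10, 1 / fs)
        v = -50.0 + 2.0 * np.sin(2 * np.pi * 0.2 * t)
        spike_times = 0.5 + np.arange(10)
        for ts in spike_times:
            v += 15.0 * np.exp(-0.5 * ((t - ts) / 0.002) ** 2)
        st_, hh = detect_spikes(v, fs=fs, threshold=-42.0)
        assert st_.size == 10
        np.testing.assert_allclose(st_, spike_times, atol=2e-3)
        np.testing.assert_allclose(hh, 15.0, atol=0.5)

    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(InputError):
            detect_spikes(np.zeros(10), times=np.array([0, 1, 2, 4, 5, 6, 7, 8, 9, 11.0]))


class TestSegmentBursts:
    def test_two_bursts_with_median_at_middle_spike(self):
        a = np.arange(7) * 0.1
        b = 3.0 + 0.6 + np.arange(7) * 0.1  # 3 s gap after last spike of a
        bursts = segment_bursts(np.concatenate([a, b + 3.0]), max_isi=1.0)
        assert len(bursts) == 2
        assert bursts[0].median == pytest.approx(a[3])
        assert bursts[1].median == pytest.approx((b + 3.0)[3])
        assert bursts[0].n_spikes == 7

    def test_single_spike_below_minimum_dropped(self):
        assert len(segment_bursts([1.0], min_spikes=4)) == 0

    def test_even_count_median_is_mean_of_middle_pair(self):
        bursts = segment_bursts([0.0, 1.0, 2.0, 3.0], max_isi=1.5)
        assert len(bursts) == 1
        assert bursts[0].median == pytest.approx(1.5)

    def test_empty_input_gives_empty_sequence(self):
        assert len(segment_bursts([])) == 0

    def test_unsorted_input_rejected(self):
        with pytest.raises(InputError):
            segment_bursts([1.0, 0.5])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=0, max_size=60, unique=True))
    def test_bursts_ordered_nonoverlapping_with_internal_medians(self, times):
        bursts = segment_bursts(sorted(times), max_isi=1.0, min_spikes=2)
        for i, b in enumerate(bursts):
            assert b.first <= b.median <= b.last
            if i:
                assert bursts[i - 1].last < b.first


class TestSlowWave:
    def test_sinusoid_height_is_peak_to_peak(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        v = 5.0 * np.sin(2 * np.pi * 0.1 * t)
        assert slow_wave_height(v, fs, cutoff=2.0) == pytest.approx(10.0, rel=0.02)

    def test_spike_ripple_removed_by_filter(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        v = 5.0 * np.sin(2 * np.pi * 0.1 * t) + 3.0 * np.sin(2 * np.pi * 30 * t)
        assert slow_wave_height(v, fs, cutoff=2.0) == pytest.approx(10.0, rel=0.05)

    def test_constant_trace_has_zero_height(self):
        assert slow_wave_height(np.full(4000, -55.0), 500.0) == pytest.approx(0.0, abs=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            slow_wave_height(np.zeros(1000), 100.0, cutoff=50.0)


class TestPhases:
    def test_phase_difference_forced_by_definition(self):
        # HE8 median at 0.49 cycle, HE12 at 0.37 -> progression 0.12
        ref = np.array([0.0, 10.0, 20.0])
        he8 = ref[:-1] + 4.9
        he12 = ref[:-1] + 3.7
        p8, p12, md = phase_of_trains(he8, he12, ref, period=10.0)
        assert p8 == pytest.approx(0.49)
        assert p12 == pytest.approx(0.37)
        assert md == pytest.approx(0.12)

    def test_identical_trains_have_zero_progression(self):
        ref = np.arange(5) * 6.0
        he = ref[:-1] + 2.0
        _, _, md = phase_of_trains(he, he.copy(), ref, period=6.0)
        assert md == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_progression_antisymmetric_under_swap(self, a, b):
        ref = np.arange(6) * 5.0
        he8 = ref[:-1] + 1.0 + (a % 2.0)
        he12 = ref[:-1] + 1.0 + (b % 2.0)
        _, _, md = phase_of_trains(he8, he12, ref, period=5.0)
        _, _, md_swapped = phase_of_trains(he12, he8, ref, period=5.0)
        if abs(md) < 0.5 - 1e-9:  # away from the wrap boundary
            assert md_swapped == pytest.approx(-md, abs=1e-12)

    def test_shift_by_full_period_changes_nothing(self):
        ref = np.arange(6) * 5.0
        he8 = ref[:-1] + 1.7
        he12 = ref[:-1] + 0.9
        r1 = phase_of_trains(he8, he12, ref, period=5.0)
        r2 = phase_of_trains(he8 + 5.0, he12 + 5.0, ref + 5.0, period=5.0)
        assert r1 == pytest.approx(r2)

    def test_wrap_into_half_open_interval(self):
        assert wrap_phase(0.6) == pytest.approx(-0.4)
        assert wrap_phase(-0.6) == pytest.approx(0.4)
        assert wrap_phase(0.5) == 0.5
        assert wrap_phase(1.2) == pytest.approx(0.2)


class TestMetricVector:
    def test_reference_simulation_yields_all_18_metrics(self, reference_sim,
                                                        clean_pattern):
        mv = lh.compute_metric_vector(reference_sim, clean_pattern)
        assert len(mv) == 18
        assert tuple(sorted(mv.values)) == tuple(sorted(METRIC_NAMES))
        assert 0 <= mv.values["HE8.peristaltic.duty_cycle"] <= 1

    def test_vector_rejects_wrong_arity(self):
        with pytest.raises(Exception):
            MetricVector({"HE8.peristaltic.duty_cycle": 0.5})


class TestMetricErrors:
    def _profile(self, target, rng):
        targets = {k: target for k in METRIC_NAMES}
        ranges = {k: rng for k in METRIC_NAMES}
        return TargetProfile(targets, ranges)

    def test_normalized_error_of_printed_progression_row(self):
        """Progression 0.0591 against target 0.07 with range 0.06 gives a
        normalized error of -0.18 (to two decimals)."""
        err = (0.0591 - 0.07) / 0.06
        assert round(err, 2) == -0.18

    def test_error_zero_at_target_and_boundary_strictness(self):
        mv = MetricVector({k: 0.5 for k in METRIC_NAMES})
        ev = metric_errors(mv, self._profile(0.5, 0.1))
        assert ev.mae == 0.0 and ev.is_good
        # |metric - target| == range -> |error| = 1, strictly not good
        # (values chosen exactly representable in binary)
        ev2 = metric_errors(mv, self._profile(0.25, 0.25))
        assert ev2.mae == 1.0
        assert not ev2.is_good

    def test_missing_target_rejected(self):
        mv = MetricVector({k: 0.5 for k in METRIC_NAMES})
        prof = self._profile(0.5, 0.1)
        del prof.targets[METRIC_NAMES[0]]
        with pytest.raises(InputError):
            metric_errors(mv, prof)

    def test_standard_ranges(self):
        assert TABLE_RANGES["duty_cycle"] == 0.10
        assert TABLE_RANGES["m_delta_phi"] == 0.06
        prof = TargetProfile.from_metric_vector(
            MetricVector({k: 0.0 for k in METRIC_NAMES})
        )
        assert prof.ranges["HE8.peristaltic.duty_cycle"] == 0.10
        assert prof.ranges["peristaltic.m_delta_phi"] == 0.06
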