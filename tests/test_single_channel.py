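import numpy as np
import pytest

from clampkit.core import Condition, PhysConstants, Segment, SegmentAnnotation, Trace
from clampkit.single_channel import (
    analyze_patch,
    apparent_n_and_po,
    build_histogram,
    chord_conductance,
    detect_closed_level,
    estimate_amplitude,
    estimate_npo,
    level_occupancies,
    npo_time_average,
)
from clampkit.synth import GatingSpec, simulate_single_channel


def idealized_trace(levels, samples_per_level=1000, i=0.38, baseline=0.0, dt=1e-3):
    """Noiseless trace stepping through the given open levels."""
    chunks = [np.full(samples_per_level, baseline - k * i) for k in levels]
    current = np.concatenate(chunks)
    duration = current.size * dt
    ann = SegmentAnnotation([Segment(0.0, duration, Condition.BASELINE)])
    return Trace(dt, current, units="pA"), ann


def with_amiloride_tail(trace, ann, baseline, tail_s=0.5):
    n_tail = int(tail_s / trace.dt)
    current = np.concatenate([trace.current, np.full(n_tail, baseline)])
    total = current.size * trace.dt
    segments = list(ann.segments)
    segments[-1] = Segment(
        segments[-1].start, total - tail_s, segments[-1].condition
    )
    segments.append(Segment(total - tail_s, total, Condition.AMILORIDE))
    return Trace(trace.dt, current, units="pA"), SegmentAnnotation(segments)


class TestClosedLevel:
    def test_constructed_baseline(self):
        trace, ann = idealized_trace([0, 1, 0], baseline=-1.0)
        trace, ann = with_amiloride_tail(trace, ann, baseline=-1.0)
        assert detect_closed_level(trace, ann) == pytest.approx(-1.0)

    def test_offset_equivariance(self):
        trace, ann = idealized_trace([0, 1])
        trace, ann = with_amiloride_tail(trace, ann, baseline=0.0)
        shifted = Trace(trace.dt, trace.current + 3.0, units="pA")
        assert detect_closed_level(shifted, ann) == pytest.approx(
            detect_closed_level(trace, ann) + 3.0
        )

    def test_missing_amiloride_segment(self):
        trace, ann = idealized_trace([0, 1])
        with pytest.raises(ValueError):
            detect_closed_level(trace, ann)

    def test_simulated_baseline_recovery(self):
        spec = GatingSpec.from_po(1, 0.3, 0.38, noise_sd=0.05)
        trace, ann = simulate_single_channel(
            spec, duration=30.0, dt=1e-3, amiloride_tail=10.0, seed=4
        )
        closed = detect_closed_level(trace, ann)
        assert closed == pytest.approx(0.0, abs=3 * 0.05 / np.sqrt(10.0 / 1e-3))


class TestHistogram:
    def test_noiseless_two_level_trace_two_bins(self):
        trace, _ = idealized_trace([0, 1], i=0.38)
        hist = build_histogram(trace, closed_level=0.0, refilter_hz=None)
        assert np.count_nonzero(hist.counts) == 2

    def test_pure_noise_single_mode(self):
        rng = np.random.default_rng(0)
        trace = Trace(1e-3, rng.normal(0, 0.05, 20000), units="pA")
        hist = build_histogram(trace, closed_level=0.0, refilter_hz=None)
        center_of_mass = np.average(hist.centers, weights=hist.counts)
        assert center_of_mass == pytest.approx(0.0, abs=0.01)

    def test_two_channel_patch_three_modes(self):
        spec = GatingSpec.from_po(2, 0.4, 0.38, noise_sd=0.03)
        trace, ann = simulate_single_channel(
            spec, duration=40.0, dt=2e-4, amiloride_tail=8.0, seed=5
        )
        closed = detect_closed_level(trace, ann)
        hist = build_histogram(trace, closed, ann=ann)
        i = estimate_amplitude(hist)
        occ = level_occupancies(hist, i)
        assert {0, 1, 2} <= set(occ)

    def test_counts_sum_to_total(self):
        trace, _ = idealized_trace([0, 1, 2])
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        assert hist.counts.sum() == hist.total_samples

    def test_invalid_bin_width(self):
        trace, _ = idealized_trace([0, 1])
        with pytest.raises(ValueError):
            build_histogram(trace, 0.0, bin_width=0.0)


class TestAmplitude:
    def test_three_evenly_spaced_modes(self):
        trace, _ = idealized_trace([0, 1, 2], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        assert estimate_amplitude(hist) == pytest.approx(0.38, abs=0.02)

    def test_two_modes(self):
        trace, _ = idealized_trace([0, 1], i=1.0)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        assert estimate_amplitude(hist) == pytest.approx(1.0, abs=0.02)

    def test_single_mode_rejected(self):
        trace, _ = idealized_trace([0], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        with pytest.raises(ValueError, match="no openings resolved"):
            estimate_amplitude(hist)

    def test_noisy_monte_carlo_recovery(self):
        spec = GatingSpec.from_po(2, 0.4, 0.38, noise_sd=0.05)
        trace, ann = simulate_single_channel(
            spec, duration=60.0, dt=2e-4, amiloride_tail=10.0, seed=6
        )
        closed = detect_closed_level(trace, ann)
        hist = build_histogram(trace, closed, ann=ann)
        assert estimate_amplitude(hist) == pytest.approx(0.38, abs=0.02)

    def test_offset_invariance(self):
        for baseline in (0.0, -2.5):
            trace, _ = idealized_trace([0, 1, 2], i=0.38, baseline=baseline)
            hist = build_histogram(trace, baseline, refilter_hz=None)
            assert estimate_amplitude(hist) == pytest.approx(0.38, abs=0.02)


class TestNPo:
    def test_half_open_single_channel(self):
        trace, _ = idealized_trace([0, 1], i=0.38)  # open half the time
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        assert estimate_npo(hist, 0.38) == pytest.approx(0.5)

    def test_two_channels_always_open(self):
        trace, _ = idealized_trace([2, 2, 1, 2], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        assert estimate_npo(hist, 0.38) == pytest.approx(1.75)

    def test_histogram_equals_time_average_oracle(self):
        # dual-route invariant on idealized traces
        trace, ann = idealized_trace([0, 1, 2, 1, 0, 1], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        via_hist = estimate_npo(hist, 0.38)
        via_time = npo_time_average(trace, 0.0, 0.38)
        assert via_hist == pytest.approx(via_time, rel=1e-12)
        assert via_time == pytest.approx(5.0 / 6.0, rel=1e-12)

    def test_simulated_binomial_npo(self):
        spec = GatingSpec.from_po(2, 0.3, 0.38, noise_sd=0.03)
        trace, ann = simulate_single_channel(
            spec, duration=120.0, dt=5e-4, amiloride_tail=10.0, seed=7
        )
        closed = detect_closed_level(trace, ann)
        hist = build_histogram(trace, closed, ann=ann)
        i = estimate_amplitude(hist)
        assert estimate_npo(hist, i) == pytest.approx(0.6, abs=0.06)


class TestApparentN:
    def test_basic_division(self):
        trace, _ = idealized_trace([0, 1, 2, 1], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        n, po = apparent_n_and_po(hist, 0.38, npo=0.8)
        assert n == 2
        assert po == pytest.approx(0.4)

    def test_more_than_three_channels_po_missing(self):
        trace, _ = idealized_trace([0, 1, 2, 3, 4], i=0.38)
        hist = build_histogram(trace, 0.0, refilter_hz=None)
        n, po = apparent_n_and_po(hist, 0.38, npo=2.0)
        assert n == 4
        assert po is None

    def test_long_single_channel_recovery(self):
        spec = GatingSpec.from_po(1, 0.3, 0.38, noise_sd=0.03)
        trace, ann = simulate_single_channel(
            spec, duration=120.0, dt=5e-4, amiloride_tail=10.0, seed=8
        )
        result = analyze_patch(trace, ann)
        assert result.apparent_n == 1
        assert result.po_app == pytest.approx(0.3, abs=0.08)

    def test_npo_not_exceeding_n(self):
        spec = GatingSpec.from_po(3, 0.5, 0.38, noise_sd=0.04)
        trace, ann = simulate_single_channel(
            spec, duration=60.0, dt=5e-4, amiloride_tail=10.0, seed=9
        )
        result = analyze_patch(trace, ann)
        assert result.npo <= result.apparent_n


class TestChordConductance:
    def test_printed_value(self):
        assert chord_conductance(0.38, -82.0) == pytest.approx(4.6, abs=0.05)
        assert round(chord_conductance(0.38, -82.0)) == 5

    def test_simple_ratio(self):
        assert chord_conductance(1.0, -100.0) == pytest.approx(10.0)

    def test_linearity(self):
        assert chord_conductance(0.76, -82.0) == pytest.approx(
            2 * chord_conductance(0.38, -82.0)
        )

    def test_zero_potential_rejected(self):
        with pytest.raises(ValueError):
            chord_conductance(0.38, 0.0)


class TestAnalyzePatch:
    def test_end_to_end_recovery(self):
        spec = GatingSpec.from_po(2, 0.3, 0.38, noise_sd=0.05)
        trace, ann = simulate_single_channel(
            spec, duration=85.0, dt=2e-4, amiloride_tail=10.0, seed=10
        )
        result = analyze_patch(trace, ann, holding=-70.0)
        assert result.i == pytest.approx(0.38, abs=0.02)
        assert result.npo == pytest.approx(0.6, abs=0.08)
        assert result.apparent_n == 2
        assert result.po_app == pytest.approx(0.3, abs=0.05)
        assert round(result.conductance_pS) == 5

    def test_lj_correction_selectable(self):
        spec = GatingSpec.from_po(1, 0.5, 0.38, noise_sd=0.04)
        trace, ann = simulate_single_channel(
            spec, duration=30.0, dt=5e-4, amiloride_tail=6.0, seed=11
        )
        corrected = analyze_patch(trace, ann, holding=-70.0, lj_correct=True)
        nominal = analyze_patch(trace, ann, holding=-70.0, lj_correct=False)
        assert corrected.conductance_pS < nominal.conductance_pS
        assert corrected.conductance_pS == pytest.approx(
            nominal.conductance_pS * 70.0 / 82.0, rel=1e-9
        )
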