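import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulseonset import (
    DetectionConfig,
    ProcessingError,
    analyze_beat_lengths,
    classify_beats,
    compute_mad,
    compute_mean_beat,
    corrupt_scan,
    correlation_distance,
    detect_pulses,
    generate_scan,
    match_onsets,
    resolve_long_beat,
    resolve_short_beat,
)
from pulseonset.beat_analysis import (
    BeatLengthStats,
    ShortBeatContext,
    relaxation_ladder,
)
from pulseonset.preprocessing import FilteredSignal, preprocess

FS = 125.0


class TestMAD:
    def test_small_examples(self):
        assert compute_mad([1, 2, 3, 4, 5]) == 1.0
        assert compute_mad([7, 7, 7, 7]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ProcessingError):
            compute_mad([])

    def test_scaled_mad_estimates_normal_sd(self, rng):
        draws = rng.standard_normal(100_000)
        assert 1.4826 * compute_mad(draws) == pytest.approx(1.0, rel=0.02)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
           st.floats(-50, 50), st.floats(-10, 10))
    def test_translation_and_scale(self, values, shift, scale):
        x = np.array(values)
        base = compute_mad(x)
        assert compute_mad(x + shift) == pytest.approx(base, abs=1e-9)
        assert compute_mad(scale * x) == pytest.approx(abs(scale) * base, rel=1e-9, abs=1e-9)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=25))
    def test_matches_bruteforce_median_of_deviations(self, values):
        med = statistics.median(values)
        expected = statistics.median([abs(v - med) for v in values])
        assert compute_mad(values) == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def _stats(self, lengths_ms):
        # 1 kHz so ms == samples
        onsets = np.concatenate(([0], np.cumsum(lengths_ms)))
        return BeatLengthStats.from_onsets(onsets)

    def test_outlier_bounds(self, config):
        stats = BeatLengthStats(
            lengths=np.array([800.0, 1200.0, 900.0, 1000.0]),
            median_length=1000.0, mad=50.0 / 1.4826, sigma_hat=50.0,
        )
        flags = classify_beats(stats, config)
        assert flags.tolist() == ["short", "long", "normal", "normal"]

    def test_fewer_than_three_beats_all_normal(self, config):
        stats = self._stats([100, 5000])
        assert classify_beats(stats, config).tolist() == ["normal", "normal"]


class TestRelaxationLadder:
    def test_exact_norms(self, config):
        assert relaxation_ladder(config) == pytest.approx(
            [0.6, 0.55, 0.5, 0.45, 0.4, 0.35]
        )

    def test_flatline_segment_exhausts_all_attempts(self, config):
        flat = FilteredSignal(np.zeros(2000), FS)
        res = resolve_long_beat(flat, 100, 1900, 30.0, FS, config)
        assert res.onset is None
        assert res.attempts == 6


class TestLongBeatRepair:
    @pytest.mark.parametrize("suppressed", [[25], [10, 30, 55]])
    def test_suppressed_onsets_recovered(self, clean_scan, suppressed):
        bad = corrupt_scan(clean_scan, suppress_pulses={k: 0.45 for k in suppressed})
        result = detect_pulses(bad.signal)
        match = match_onsets(bad.truth.onsets, result.onsets, FS)
        assert match.fn_onsets.size == 0 and match.fp_onsets.size == 0
        assert np.max(np.abs(match.offsets_ms)) <= 10.0
        assert result.beat_analysis.onsets_added == len(suppressed)
        assert result.beat_analysis.max_relaxation_attempts <= 6

    def test_two_adjacent_misses_need_two_iterations(self, clean_scan):
        bad = corrupt_scan(clean_scan, suppress_pulses={30: 0.45, 31: 0.45})
        result = detect_pulses(bad.signal)
        match = match_onsets(bad.truth.onsets, result.onsets, FS)
        assert match.fn_onsets.size == 0 and match.fp_onsets.size == 0
        assert result.beat_analysis.iterations >= 2
        assert result.beat_analysis.onsets_added == 2

    def test_added_onsets_lie_inside_their_long_beat(self, clean_scan):
        bad = corrupt_scan(clean_scan, suppress_pulses={20: 0.45})
        first = detect_pulses(bad.signal, run_beat_analysis=False,
                              run_alignment=False)
        full = detect_pulses(bad.signal, run_alignment=False)
        added = sorted(set(full.onsets) - set(first.onsets))
        assert len(added) == 1
        k = np.searchsorted(first.onsets, added[0])
        assert first.onsets[k - 1] < added[0] < first.onsets[k]


class TestMeanBeat:
    def test_identical_beats_average_to_themselves(self):
        beat = np.sin(np.linspace(0, 2 * np.pi, 50))
        y = FilteredSignal(np.tile(beat, 5), FS)
        onsets = np.arange(0, 251, 50)
        mean = compute_mean_beat(y, onsets, 25)
        assert mean.length == 50
        assert np.allclose(mean.samples, beat)
        assert mean.upslope.size == 25

    def test_truncate_and_pad_rules(self):
        y = FilteredSignal(np.array([0, 1, 2, 3, 0, 1, 2, 3, 4, 5, 0.0]), FS)
        onsets = np.array([0, 4, 10])  # beats of length 4 and 6, target 5
        mean = compute_mean_beat(y, onsets, 3)
        padded_short = [0, 1, 2, 3, 3]  # last value repeated
        truncated_long = [0, 1, 2, 3, 4]
        expected = (np.array(padded_short) + np.array(truncated_long)) / 2
        assert np.allclose(mean.samples, expected)

    def test_single_beat(self):
        y = FilteredSignal(np.arange(8.0), FS)
        mean = compute_mean_beat(y, np.array([0, 5]), 2)
        assert np.allclose(mean.samples, [0, 1, 2, 3, 4])

    def test_no_complete_beats_rejected(self):
        with pytest.raises(ProcessingError):
            compute_mean_beat(FilteredSignal(np.arange(8.0), FS), np.array([3]), 2)


class TestCorrelationDistance:
    def test_anchor_values(self):
        assert correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
        assert correlation_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)
        assert correlation_distance([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(2.0)
        # orthogonal after centering
        assert correlation_distance([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(1.0)

    def test_constant_vector_defined_as_uncorrelated(self):
        assert correlation_distance([5, 5, 5], [1, 2, 3]) == 1.0

    def test_length_equalized_by_tail_truncation(self):
        assert correlation_distance([1, 2, 3, 99, -7], [1, 2, 3]) == pytest.approx(0.0)

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.floats(0.1, 10), st.floats(-20, 20),
    )
    def test_symmetry_and_affine_invariance(self, u, v, scale, shift):
        u, v = np.array(u), np.array(v)
        d = correlation_distance(u, v)
        assert correlation_distance(v, u) == pytest.approx(d, abs=1e-9)
        assert correlation_distance(scale * u + shift, v) == pytest.approx(d, abs=1e-6)


class TestShortBeatRepair:
    def test_spike_split_beats_are_merged_back(self, clean_scan):
        spikes = [clean_scan.truth.onsets[k] / FS + 0.55 for k in (15, 40, 70)]
        bad = corrupt_scan(clean_scan, insert_spikes_s=spikes)
        first = detect_pulses(bad.signal, run_beat_analysis=False,
                              run_alignment=False)
        assert len(first.onsets) > len(bad.truth)  # spikes bait extra onsets
        full = detect_pulses(bad.signal)
        match = match_onsets(bad.truth.onsets, full.onsets, FS)
        assert match.fp_onsets.size == 0 and match.fn_onsets.size == 0

    def test_normal_shaped_short_beat_untouched(self, config):
        # a premature but morphologically normal beat: a regular pulse cut
        # short, so its correlation distance from the mean beat is ~0
        from pulseonset.synthetic import MORPHOLOGY_PRESETS, generate_pulse

        pulse = generate_pulse(MORPHOLOGY_PRESETS["normal"], 857.0, FS)
        short = pulse[: int(0.7 * pulse.size)]
        pieces = [pulse] * 4 + [short] + [pulse] * 4
        y = FilteredSignal(np.concatenate(pieces), FS)
        onsets = np.concatenate(([0], np.cumsum([p.size for p in pieces])))
        lengths = np.diff(onsets)
        i_short = int(np.argmin(lengths))
        mean = compute_mean_beat(y, onsets, 25)
        context = ShortBeatContext(
            index=i_short, l_short=int(lengths[i_short]),
            l_before=int(lengths[i_short - 1]), l_after=int(lengths[i_short + 1]),
        )
        edited, action = resolve_short_beat(
            y, context, mean, onsets, float(np.median(lengths)), config
        )
        assert action == "none"
        assert edited.tolist() == onsets.tolist()

    def test_garbage_short_beat_deleted_outright(self, config):
        # short beat anticorrelated with the mean beat, no favorable merge
        beat = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        garbage = -beat[:70]
        pieces = [beat] * 3 + [garbage] + [beat] * 3
        y = FilteredSignal(np.concatenate(pieces), FS)
        onsets = np.concatenate(([0], np.cumsum([p.size for p in pieces])))
        lengths = np.diff(onsets)
        i_short = int(np.argmin(lengths))
        mean = compute_mean_beat(y, onsets, 25)
        context = ShortBeatContext(
            index=i_short, l_short=70, l_before=100, l_after=100
        )
        edited, action = resolve_short_beat(
            y, context, mean, onsets, float(np.median(lengths)), config
        )
        assert action == "delete"
        assert len(edited) == len(onsets) - 1
        assert onsets[i_short] not in edited


class TestIterationControl:
    def test_clean_scan_converges_immediately(self, clean_scan, config):
        filtered, mdf = preprocess(clean_scan.signal, config)
        from pulseonset import detect_onsets

        beats, _ = detect_onsets(filtered, mdf, FS, config)
        result = analyze_beat_lengths(filtered, beats, FS, config)
        assert result.iterations == 1
        assert result.onsets_added == 0 and result.onsets_removed == 0
        assert result.onsets.tolist() == [b.onset_index for b in beats]

    def test_iteration_cap_enforced(self, clean_scan):
        # two nested misses need two iterations; a cap of 1 stops after one
        bad = corrupt_scan(clean_scan, suppress_pulses={30: 0.45, 31: 0.45})
        capped = detect_pulses(bad.signal,
                               DetectionConfig(max_iterations=1),
                               run_alignment=False)
        assert capped.beat_analysis.iterations == 1
        assert capped.beat_analysis.onsets_added == 1  # only one recovered
        full = detect_pulses(bad.signal, run_alignment=False)
        assert full.beat_analysis.onsets_added == 2
        assert full.beat_analysis.iterations <= 10

    def test_convergence_means_last_iteration_made_no_edits(self, clean_scan):
        bad = corrupt_scan(clean_scan, suppress_pulses={10: 0.45})
        result = detect_pulses(bad.signal, run_alignment=False)
        ba = result.beat_analysis
        # edits all happened before the final (quiet) iteration
        assert ba.iterations < ba.onsets_added + 2 + 1
        assert np.all(np.diff(result.onsets) > 0)
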