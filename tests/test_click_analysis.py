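"""Detection, the sliding-window duty-cycle statistic, and species comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_uniform_clicks
from tymbal.click_analysis import (
    DetectionConfig,
    compare_variances,
    detect_clicks,
    duty_cycle_profile,
    score_clicks,
    score_individual,
    summarize_species,
)
from tymbal.stimulus_builder import StimulusSpec, build_stimulus
from tymbal.tymbal_model import (
    ClickEvent,
    IndividualProfile,
    Recording,
    synthesize_click_train,
)


class TestDetectClicks:
    def test_silent_recording_empty(self):
        assert detect_clicks(Recording(np.zeros(50_000))) == []

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            detect_clicks(Recording(np.zeros(0)))

    def test_low_sample_rate_for_highpass_rejected(self):
        cfg = DetectionConfig(highpass_cutoff=5_000.0)
        with pytest.raises(ValueError, match="high-pass"):
            detect_clicks(Recording(np.zeros(1000), sample_rate=8_000), cfg)

    def test_ground_truth_round_trip(self, train_45):
        """Every synthesized click detects once, onset within 0.1 ms of truth."""
        events = detect_clicks(train_45)
        truth = train_45.ground_truth
        assert len(events) == len(truth)
        onset_errors = [abs(e.onset - t.onset) for e, t in zip(events, truth)]
        assert max(onset_errors) < 0.1e-3

    def test_white_noise_detects_as_one_spanning_event(self):
        rec = build_stimulus(StimulusSpec("white_noise"))
        events = detect_clicks(rec)
        assert len(events) == 1
        assert events[0].duration >= 0.99 * 0.6


class TestDutyCycleProfile:
    def test_150_clicks_in_window_gives_45(self):
        clicks = make_uniform_clicks(150, duration=0.0003, spacing=0.0006)
        prof = duty_cycle_profile(clicks)
        assert prof.reported_dc == pytest.approx(45.0)

    def test_no_clicks_all_zero(self):
        prof = duty_cycle_profile([])
        assert prof.reported_dc == 0.0
        assert np.all(prof.dc_values == 0.0)

    def test_mixed_durations_equal_summed_durations(self):
        clicks = make_uniform_clicks(10, duration=0.0002, spacing=0.001) + make_uniform_clicks(
            10, duration=0.0004, spacing=0.001, start=0.05
        )
        prof = duty_cycle_profile(clicks)
        assert prof.reported_dc == pytest.approx(6.0)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            duty_cycle_profile([], window_length=0.0)

    def test_durations_clipped_to_window_cap_at_100(self):
        # One event longer than the window: clipping keeps dc at 100.
        prof = duty_cycle_profile([ClickEvent(0.0, 0.6)])
        assert prof.dc_values.max() == pytest.approx(100.0)
        assert np.all(prof.dc_values <= 100.0 + 1e-9)

    @given(shift_steps=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_time_shift_invariance(self, shift_steps):
        """Shifting all clicks by whole window steps leaves the score unchanged.

        (For sub-step shifts the discretized window grid re-aligns against the
        clicks, so exact invariance holds on step multiples.)
        """
        shift = shift_steps * 0.001
        clicks = make_uniform_clicks(40, duration=0.0003, spacing=0.0008)
        shifted = [ClickEvent(c.onset + shift, c.duration) for c in clicks]
        assert score_clicks(shifted) == pytest.approx(score_clicks(clicks), abs=1e-9)


class TestScoreIndividual:
    def test_synthesized_target_recovered(self):
        rec = synthesize_click_train(IndividualProfile("x", 45.0, seed=11), 0.4)
        assert score_individual(rec) == pytest.approx(45.0, abs=1.0)

    def test_silent_recording_scores_zero(self):
        assert score_individual(Recording(np.zeros(50_000))) == 0.0

    def test_max_count_window_wins_across_recordings(self):
        """Selection is by click count, not duty cycle, across recordings.

        40 long clicks reach 30% DC; 50 shorter clicks reach 28% DC. The
        count rule reports the 28% window.
        """

        def train(n, duration):
            clicks = make_uniform_clicks(n, duration=duration, spacing=0.1 / (n + 1))
            fs = 250_000
            samples = np.zeros(int(0.12 * fs))
            from tymbal.tymbal_model import SweepSpec, synthesize_click

            wave = synthesize_click(duration, SweepSpec(90_000, 45_000), fs)
            for c in clicks:
                i = int(round(c.onset * fs))
                samples[i : i + len(wave)] += 0.8 * wave
            return Recording(samples, fs)

        rec_30 = train(40, 0.00075)  # 40 x 0.75 ms = 30%
        rec_28 = train(50, 0.00056)  # 50 x 0.56 ms = 28%
        dc = score_individual([rec_30, rec_28])
        assert dc == pytest.approx(28.0, abs=1.5)
        assert score_individual(rec_30) == pytest.approx(30.0, abs=1.5)

    @pytest.mark.parametrize("target", [5, 25, 45, 70])
    def test_detector_agrees_with_ground_truth_scoring(self, target):
        rec = synthesize_click_train(IndividualProfile("x", float(target), seed=2), 0.4)
        assert score_individual(rec) == pytest.approx(score_clicks(rec.ground_truth), abs=1.0)


class TestSummarizeSpecies:
    def test_single_value_sd_undefined(self):
        s = summarize_species([41.0], "bt")
        assert s.mean_dc == 41.0 and s.sd_dc is None and s.max_dc == 41.0

    def test_hand_arithmetic(self):
        s = summarize_species([10.0, 20.0, 30.0], "bt")
        assert s.mean_dc == pytest.approx(20.0)
        assert s.sd_dc == pytest.approx(10.0)
        assert s.max_dc == 30.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_species([], "bt")

    def test_truncated_normal_cohort_mean_within_sampling_error(self):
        from scipy.stats import truncnorm

        rng = np.random.default_rng(5)
        a, b = (21 - 41) / 13, (67 - 41) / 13
        draws = truncnorm.rvs(a, b, loc=41, scale=13, size=30, random_state=rng)
        s = summarize_species(draws, "bt")
        assert s.mean_dc == pytest.approx(41.0, abs=5.0)


class TestCompareVariances:
    def test_identical_groups_null(self):
        g = [10.0, 20.0, 30.0, 40.0]
        res = compare_variances(g, g)
        assert res.z == 0.0 and res.p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_variances([1.0], [1.0, 2.0])

    def test_zero_variance_degenerate(self):
        res = compare_variances([5.0, 5.0, 5.0], [7.0, 7.0])
        assert res.degenerate

    def test_type_one_error_calibrated_under_null(self):
        """p-values approximately uniform for equal-variance groups."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(400):
            a = rng.normal(41, 13, size=500)
            b = rng.normal(30, 13, size=500)
            pvals.append(compare_variances(a, b).p)
        pvals = np.array(pvals)
        # Rejection rate at alpha=0.05 close to nominal; mean p near 0.5.
        assert abs((pvals < 0.05).mean() - 0.05) < 0.035
        assert abs(pvals.mean() - 0.5) < 0.06

    def test_power_against_unequal_spread(self):
        """sd 13 (n=30) vs sd 6 (n=12) rejects in most replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(41, 13, size=30)
            b = rng.normal(30, 6, size=12)
            if compare_variances(a, b).p < 0.05:
                rejections += 1
        assert rejections / n_sim > 0.5
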