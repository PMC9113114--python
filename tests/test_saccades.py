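"""Saccade-scoring tests: filtering, velocity, event detection, the
primary-saccade / anticipatory / 20%-of-distance rules, blink handling,
condition summaries and symmetry properties."""

import numpy as np
import pandas as pd
import pytest

from cerebmotor.saccades import (
    GazeTimeSeries,
    SaccadeConfig,
    SaccadeEvent,
    SaccadeExclusion,
    compute_velocity,
    detect_blinks,
    detect_saccades,
    filter_gaze,
    score_trial,
    score_trials,
    select_primary,
    summarize_conditions,
)
from cerebmotor.simulate import SaccadeTrialSpec, generate_saccade_trial
from cerebmotor.simulate.gaze import _logistic_step

FS = 500.0
DT = 1000.0 / FS


def make_series(x, target=12.0, onset=1000.0, y=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) * DT
    return GazeTimeSeries(
        time=t,
        x=x,
        y=np.zeros_like(x) if y is None else y,
        target_amplitude=target,
        target_onset_time=onset,
    )


def two_step_series(amp1=2.0, amp2=11.0, target=12.0):
    """Fixation, a small step at 1300 ms, a large step at 1600 ms."""
    t = np.arange(0, 2500.0, DT)
    x = _logistic_step(t, 1300.0, amp1) + _logistic_step(t, 1600.0, amp2)
    return GazeTimeSeries(
        time=t, x=x, y=np.zeros_like(x), target_amplitude=target, target_onset_time=1000.0
    )


class TestVelocity:
    def test_linear_motion_velocity(self):
        t = np.arange(0, 1000.0, DT)
        s = make_series(10.0 * t / 1000.0)
        v = compute_velocity(s)
        assert np.allclose(v, 10.0, atol=1e-6)

    def test_constant_position_zero_velocity(self):
        s = make_series(np.full(500, 3.0))
        assert np.allclose(compute_velocity(s), 0.0)

    def test_peak_velocity_matches_annotation(self):
        tr = generate_saccade_trial(SaccadeTrialSpec(target_amplitude=24.0), seed=0)
        v = compute_velocity(filter_gaze(tr))
        assert np.max(np.abs(v)) == pytest.approx(
            tr.annotations["true_peak_velocity"], rel=0.05
        )


class TestFilter:
    def test_constant_trace_unchanged(self):
        s = make_series(np.full(1000, 12.0))
        out = filter_gaze(s)
        assert np.allclose(out.x, 12.0, atol=1e-9)

    def test_high_frequency_jitter_attenuated_10x(self):
        t = np.arange(0, 2000.0, DT)
        jitter = 0.2 * np.sin(2 * np.pi * 100.0 * t / 1000.0)
        s = make_series(5.0 + jitter)
        out = filter_gaze(s)
        mid = out.x[200:-200]
        assert (mid.max() - mid.min()) / 2 < 0.02

    def test_noiseless_saccade_landing_preserved(self):
        tr = generate_saccade_trial(
            SaccadeTrialSpec(target_amplitude=24.0, gain=0.9), seed=0
        )
        out = filter_gaze(tr)
        assert abs(out.x[-1] - tr.x[-1]) < 0.05


class TestDetection:
    def test_stationary_trace_yields_no_events(self):
        s = make_series(np.full(1000, 0.0))
        assert detect_saccades(s, compute_velocity(s)) == []

    def test_single_saccade_onset_within_one_sample(self):
        tr = generate_saccade_trial(SaccadeTrialSpec(target_amplitude=12.0), seed=0)
        sm = filter_gaze(tr)
        events = detect_saccades(sm, compute_velocity(sm))
        assert len(events) == 1
        assert events[0].onset_time == pytest.approx(
            tr.annotations["true_onset_ms"], abs=3 * DT
        )
        assert events[0].amplitude == pytest.approx(12.0, abs=0.3)

    def test_primary_and_corrective_in_time_order(self):
        tr = generate_saccade_trial(
            SaccadeTrialSpec(target_amplitude=24.0, gain=0.8, corrective=(100.0, 0.9)),
            seed=0,
        )
        sm = filter_gaze(tr)
        events = detect_saccades(sm, compute_velocity(sm))
        assert len(events) == 2
        assert events[0].onset_time < events[1].onset_time


class TestPrimaryRule:
    def test_small_first_saccade_skipped_for_primary(self):
        # 2.0 deg < 20% of 12 deg: the second (11 deg) saccade is primary,
        # landing at 13 deg, so error is 1.0 deg
        s = two_step_series()
        score = score_trial(s)
        assert score.valid
        assert score.primary.onset_time > 1500.0
        assert score.error == pytest.approx(1.0, abs=0.1)

    def test_exactly_20pct_amplitude_qualifies(self):
        events = [SaccadeEvent(1200.0, 1240.0, 2.4, 200.0, 200.0)]
        s = make_series(np.full(1500, 0.0), target=12.0, onset=1000.0)
        score = select_primary(events, s)
        assert score.valid  # "at least 20%" is inclusive

    def test_just_below_20pct_is_no_primary(self):
        events = [SaccadeEvent(1200.0, 1240.0, 2.3, 200.0, 200.0)]
        s = make_series(np.full(1500, 0.0), target=12.0, onset=1000.0)
        score = select_primary(events, s)
        assert not score.valid
        assert score.exclusion_reason is SaccadeExclusion.NO_PRIMARY

    def test_latency_of_exactly_70ms_is_anticipatory(self):
        events = [SaccadeEvent(1070.0, 1110.0, 11.0, 400.0, 70.0)]
        s = make_series(np.full(1500, 0.0), target=12.0, onset=1000.0)
        score = select_primary(events, s)
        assert not score.valid
        assert score.exclusion_reason is SaccadeExclusion.ANTICIPATORY

    def test_latency_above_70ms_is_kept(self):
        events = [SaccadeEvent(1072.0, 1112.0, 11.0, 400.0, 72.0)]
        s = make_series(np.full(1500, 11.0), target=12.0, onset=1000.0)
        score = select_primary(events, s)
        assert score.valid

    def test_wrong_direction_saccade_not_primary(self):
        events = [SaccadeEvent(1200.0, 1240.0, -11.0, -400.0, 200.0)]
        s = make_series(np.full(1500, 0.0), target=12.0, onset=1000.0)
        score = select_primary(events, s)
        assert score.exclusion_reason is SaccadeExclusion.NO_PRIMARY
        loose = select_primary(
            events, s, SaccadeConfig(require_direction_congruence=False)
        )
        assert loose.valid

    def test_scored_error_equals_gain_error_for_noiseless_trials(self):
        rng = np.random.default_rng(40)
        for _ in range(40):
            amp = float(rng.choice([12.0, 24.0]) * rng.choice([-1, 1]))
            gain = float(rng.uniform(0.8, 1.1))
            tr = generate_saccade_trial(
                SaccadeTrialSpec(target_amplitude=amp, gain=gain),
                rng,
            )
            score = score_trial(tr)
            assert score.valid
            tol = tr.annotations["true_peak_velocity"] * (DT / 1000.0)
            assert score.error == pytest.approx(abs(gain - 1) * abs(amp), abs=tol)


class TestBlinks:
    def test_clean_trace_has_no_spans(self):
        tr = generate_saccade_trial(SaccadeTrialSpec(target_amplitude=12.0), seed=0)
        assert detect_blinks(tr) == []

    def test_blink_in_response_window_excludes_trial(self):
        tr = generate_saccade_trial(
            SaccadeTrialSpec(target_amplitude=12.0, blink=(300.0, 100.0)), seed=0
        )
        score = score_trial(tr)
        assert not score.valid
        assert score.exclusion_reason is SaccadeExclusion.BLINK

    def test_blink_during_fixation_only_is_tolerated(self):
        tr = generate_saccade_trial(
            SaccadeTrialSpec(target_amplitude=12.0, blink=(-800.0, 100.0)), seed=0
        )
        score = score_trial(tr)
        assert score.valid


class TestSymmetry:
    def test_mirrored_trial_scores_identically(self):
        spec = SaccadeTrialSpec(target_amplitude=24.0, gain=0.92)
        tr = generate_saccade_trial(spec, seed=4)
        mirrored = GazeTimeSeries(
            time=tr.time,
            x=-tr.x,
            y=tr.y,
            target_amplitude=-tr.target_amplitude,
            target_onset_time=tr.target_onset_time,
        )
        a, b = score_trial(tr), score_trial(mirrored)
        assert a.valid and b.valid
        assert a.error == pytest.approx(b.error, abs=1e-9)
        assert a.primary.latency == pytest.approx(b.primary.latency, abs=1e-9)
        assert a.direction_cell != b.direction_cell


class TestSummaries:
    def _scores(self, errors, amp=12.0, direction="rightward"):
        sign = 1 if direction == "rightward" else -1
        return pd.DataFrame(
            {
                "participant_id": "P1",
                "trial_id": range(len(errors)),
                "amplitude": amp,
                "direction": direction,
                "valid": True,
                "error": errors,
            }
        )

    def test_identical_errors_have_zero_sd(self):
        out = summarize_conditions(self._scores([1.0, 1.0, 1.0]))
        cell = out[(out["amplitude"] == 12.0) & (out["direction"] == "rightward")]
        assert cell["mean_error"].iloc[0] == 1.0
        assert cell["error_sd"].iloc[0] == 0.0

    def test_two_trial_sample_sd(self):
        out = summarize_conditions(self._scores([0.0, 2.0]))
        cell = out[(out["amplitude"] == 12.0) & (out["direction"] == "rightward")]
        assert cell["mean_error"].iloc[0] == 1.0
        assert cell["error_sd"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_empty_cell_flagged_with_null_metrics(self):
        out = summarize_conditions(self._scores([1.0, 1.5]))
        empty = out[(out["amplitude"] == 24.0) & (out["direction"] == "leftward")]
        assert empty["n_valid"].iloc[0] == 0
        assert np.isnan(empty["mean_error"].iloc[0])

    def test_error_sd_tracks_gain_noise(self):
        """With gain ~ N(g, s), landing error SD per cell is |target| * s."""
        rng = np.random.default_rng(50)
        sigma_g = 0.03
        trials = []
        for i in range(200):
            gain = float(rng.normal(0.90, sigma_g))
            trials.append(
                generate_saccade_trial(
                    SaccadeTrialSpec(target_amplitude=12.0, gain=gain), rng, trial_id=i
                )
            )
        scores = score_trials(trials)
        assert scores["valid"].all()
        sd = scores["error"].std(ddof=1)
        assert sd == pytest.approx(12.0 * sigma_g, rel=0.20)
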