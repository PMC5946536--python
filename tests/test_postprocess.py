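"""Majority vote and MAV threshold-switch post-processing."""

from collections import Counter

import numpy as np
import pytest

from emgpr import (STILL, ConfigError, ParameterError, SimConfig,
                   ThresholdConfig, assessment_schedule, derive_thresholds,
                   majority_vote, run_pipeline, simulate, threshold_switch)
from emgpr.postprocess import DecisionStream


class TestThresholdSwitch:
    MAVS = {"hand close": 0.25, "hand open": 0.05, "wrist rotation": 0.12,
            "elbow flexion": 0.3, "elbow extension": 0.15}

    def test_above_threshold_emits_motion(self, st_thresholds):
        d = threshold_switch("hand close", self.MAVS, st_thresholds)
        assert d.output == "hand close"
        assert d.mav == pytest.approx(0.25)

    def test_below_threshold_stays_still(self, st_thresholds):
        d = threshold_switch("hand open", self.MAVS, st_thresholds)
        assert d.output == STILL
        assert d.raw_class == "hand open"

    def test_exact_threshold_stays_still(self):
        cfg = ThresholdConfig({"hand close": 0.25})
        d = threshold_switch("hand close", self.MAVS, cfg)
        assert d.output == STILL  # strictly "higher than"

    def test_unconfigured_motion_is_config_error(self):
        cfg = ThresholdConfig({"hand close": 0.2})
        with pytest.raises(ConfigError):
            threshold_switch("hand open", self.MAVS, cfg)

    def test_missing_mav_is_config_error(self, st_thresholds):
        with pytest.raises(ConfigError):
            threshold_switch("hand open", {"hand close": 0.3}, st_thresholds)


class TestDeriveThresholds:
    def test_lower_and_higher_sets(self, st_thresholds):
        lt = derive_thresholds(st_thresholds, 0.8)
        ht = derive_thresholds(st_thresholds, 1.2)
        assert lt.name == "LT" and ht.name == "HT"
        assert lt.thresholds["hand close"] == pytest.approx(0.16)
        assert ht.thresholds["wrist rotation"] == pytest.approx(0.12)

    def test_identity_factor(self, st_thresholds):
        same = derive_thresholds(st_thresholds, 1.0)
        assert same.thresholds == pytest.approx(st_thresholds.thresholds)

    def test_nonpositive_factor_rejected(self, st_thresholds):
        with pytest.raises(ParameterError):
            derive_thresholds(st_thresholds, 0.0)

    def test_positive_thresholds_enforced(self):
        with pytest.raises(ParameterError):
            ThresholdConfig({"hand close": 0.0})


def vote_oracle(stream, L, labels, prev_tb=True):
    """Brute-force sliding-window mode with the documented tie-breaks."""
    out, prev = [], None
    for t in range(len(stream)):
        window = stream[max(0, t - L + 1): t + 1]
        counts = Counter(window)
        top = max(counts.values())
        modes = [lab for lab in counts if counts[lab] == top]
        if prev in modes:
            out.append(prev)
        else:
            out.append(min(modes, key=labels.index))
        prev = out[-1]
    return out


class TestMajorityVote:
    def test_two_of_three(self):
        assert majority_vote(["A", "A", "B"], 3)[-1] == "A"

    def test_length_one_is_identity(self):
        stream = list("ABBACCA")
        assert majority_vote(stream, 1) == stream

    def test_invalid_length_rejected(self):
        with pytest.raises(ParameterError):
            majority_vote(["A"], 0)

    def test_matches_sliding_mode_oracle(self, rng):
        labels = list("ABCDE")
        stream = [labels[i] for i in rng.integers(0, 5, size=400)]
        assert majority_vote(stream, 5, labels) == vote_oracle(stream, 5, labels)

    def test_single_deviant_inside_a_run_never_flips_it(self):
        for L in (3, 5, 10):
            for pos in range(L, 2 * L):  # deviant after the run is established
                stream = ["A"] * (3 * L)
                stream[pos] = "B"
                out = majority_vote(stream, L, ["A", "B"])
                assert all(o == "A" for o in out), (L, pos)

    def test_tie_prefers_previous_output(self):
        # queue [A, B] at t=1: tie; previous output A wins
        assert majority_vote(["A", "B"], 2, ["A", "B"]) == ["A", "A"]
        # and symmetrically previous output B wins the same tie
        assert majority_vote(["B", "A"], 2, ["A", "B"]) == ["B", "B"]


@pytest.fixture(scope="module")
def sim_stream(trained_model, default_cfg):
    sched = assessment_schedule(default_cfg)
    rec = simulate(SimConfig(seed=777), sched)
    return rec, sched


class TestRunPipeline:
    def test_mode_none_is_raw(self, sim_stream, trained_model):
        rec, _ = sim_stream
        ds = run_pipeline(rec, trained_model, mode="none")
        assert ds.outputs == ds.raw
        assert ds.window_len == 256 and ds.step == 128

    def test_threshold_limit_recovers_raw(self, sim_stream, trained_model):
        rec, _ = sim_stream
        tiny = ThresholdConfig({m: 1e-12 for m in trained_model.labels})
        ds = run_pipeline(rec, trained_model, mode="threshold", thresholds=tiny)
        assert ds.outputs == ds.raw  # every MAV strictly positive

    def test_rest_only_segment_is_all_still(self, trained_model, default_cfg,
                                            st_thresholds):
        from emgpr import MotionSchedule, ScheduleEntry
        sched = MotionSchedule([ScheduleEntry("REST", 0.0, 3.0)])
        rec = simulate(SimConfig(seed=5), sched, duration_s=3.0)
        ds = run_pipeline(rec, trained_model, mode="threshold",
                          thresholds=st_thresholds)
        assert set(ds.outputs) == {STILL}

    def test_gating_soundness(self, sim_stream, trained_model, st_thresholds):
        """Every emitted motion m satisfies V_m > T_m in its window."""
        rec, _ = sim_stream
        ds = run_pipeline(rec, trained_model, mode="threshold",
                          thresholds=st_thresholds)
        emitted = [d for d in ds.decisions if d.output != STILL]
        assert emitted  # the hold segments do fire
        for d in emitted:
            assert d.output == d.raw_class
            assert d.mav > st_thresholds.thresholds[d.output]

    def test_threshold_monotonicity(self, sim_stream, trained_model,
                                    st_thresholds):
        """Raising any T_i only converts motion-i outputs to STILL."""
        rec, _ = sim_stream
        for motion in trained_model.labels:
            prev_outputs = None
            for t in np.linspace(0.05, 0.6, 10):
                cfg = ThresholdConfig(dict(st_thresholds.thresholds,
                                           **{motion: float(t)}))
                outputs = run_pipeline(rec, trained_model, mode="threshold",
                                       thresholds=cfg).outputs
                if prev_outputs is not None:
                    for before, after in zip(prev_outputs, outputs):
                        if after != before:
                            assert before == motion and after == STILL
                prev_outputs = outputs

    def test_layout_mismatch_rejected(self, sim_stream, trained_model):
        rec, _ = sim_stream
        three_ch = rec.samples[:, :3]
        from emgpr import EMGRecording
        small = EMGRecording(three_ch, rec.fs, rec.channel_labels[:3],
                             {c: rec.motion_map[c] for c in rec.channel_labels[:3]})
        with pytest.raises(ConfigError):
            run_pipeline(small, trained_model)

    def test_stream_csv_round_trip(self, sim_stream, trained_model, tmp_path):
        rec, _ = sim_stream
        ds = run_pipeline(rec, trained_model, mode="vote", vote_len=5)
        path = tmp_path / "stream.csv"
        ds.to_csv(path)
        back = DecisionStream.from_csv(path)
        assert back.fs == ds.fs
        assert back.window_len == ds.window_len
        assert back.mode == ds.mode
        assert [d.output for d in back.decisions] == ds.outputs
        assert [d.window_start for d in back.decisions] == \
            [d.window_start for d in ds.decisions]
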