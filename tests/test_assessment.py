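"""Assessment blueprint: window likelihoods, movement clipping, timing
ratios, transition anomalies, error direction and outcome aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rehabmotion.assessment import (
    AssessConfig, AssessmentFlag, IncoordinationError, ModelRegistry,
    MovementClipping, NoMovementError, RegistryEntry, UnsupportedModelError,
    aggregate_outcome, build_reference_profile, canonical_registry,
    classify_movement, clip_movement, correct_trials,
    detect_transition_anomalies, error_direction, loso_train, report_ratio,
    run_length_encode, sliding_window_likelihood, smooth_path, symmetry_ratio,
    synchronicity_ratio,
)
from rehabmotion.features import FeatureSeries, extract_features, assessment_preset
from rehabmotion.hmm import GaussianHMM, sample_sequence, viterbi_path
from rehabmotion.skeleton import TherapistLabel

MODEL = GaussianHMM(
    2, [0.9, 0.1], [[0.95, 0.05], [0.05, 0.95]],
    [[0.0], [4.0]], [[0.5], [0.5]],
)


def make_path(*segments):
    """Build a state path from (state, length) pairs."""
    return np.concatenate([np.full(l, s, dtype=np.int64) for s, l in segments])


class TestSlidingWindow:
    def test_tiling_arithmetic(self):
        obs = sample_sequence(MODEL, 200, seed=0)
        trace = sliding_window_likelihood(MODEL, obs, window_len=60,
                                          stride=200 - 60)
        assert len(trace.values) == 2
        assert list(trace.window_starts) == [0, 140]

    def test_self_sampled_values_are_typical(self):
        """Windows of a self-sampled sequence are mutually consistent:
        nearly all within 3 MAD of the median, none catastrophically out."""
        obs = sample_sequence(MODEL, 600, seed=1)
        trace = sliding_window_likelihood(MODEL, obs, window_len=60, stride=15)
        med = np.median(trace.values)
        mad = np.median(np.abs(trace.values - med))
        dev = np.abs(trace.values - med)
        assert np.mean(dev <= 3 * mad) >= 0.9
        assert np.all(dev <= 6 * mad)

    def test_perturbed_window_attains_minimum(self):
        obs = sample_sequence(MODEL, 300, seed=2)
        obs[120:180] += 10 * np.sqrt(0.5)  # 10 state-sd displacement
        trace = sliding_window_likelihood(MODEL, obs, window_len=60, stride=15)
        assert trace.window_starts[trace.min_index] == 120

    def test_window_len_validated(self):
        with pytest.raises(Exception):
            sliding_window_likelihood(MODEL, sample_sequence(MODEL, 50, seed=0),
                                      window_len=1)


class TestClipping:
    def _sway(self, rise=90, hold=60, fall=90, rest=60, amp=0.03):
        """Signed trunk sway speed of a raised-cosine out-and-back movement."""
        n = 2 * rest + rise + hold + fall
        disp = np.zeros(n)
        t = np.arange(rise) / rise
        disp[rest:rest + rise] = 0.5 * (1 - np.cos(np.pi * t))
        disp[rest + rise:rest + rise + hold] = 1.0
        t = np.arange(fall) / fall
        disp[rest + rise + hold:rest + rise + hold + fall] = 0.5 * (1 + np.cos(np.pi * t))
        speed = np.gradient(-amp * disp)
        phase = make_path((0, rest), (1, rise), (2, hold), (3, fall), (0, rest))
        return speed, phase

    def test_peak_found_at_movement_center(self):
        speed, phase = self._sway()
        clip = clip_movement(speed, phase)
        assert clip.peak_frame == pytest.approx(60 + 90 + 30, abs=2)
        assert clip.start_frame < clip.peak_frame < clip.end_frame

    def test_all_rest_path_is_no_movement(self):
        with pytest.raises(NoMovementError):
            clip_movement(np.zeros(100), np.zeros(100, dtype=int))

    def test_clip_ordering_invariant(self):
        with pytest.raises(NoMovementError):
            MovementClipping(start_frame=50, peak_frame=40, end_frame=100)

    def test_symmetric_trial_ratio_is_one(self):
        speed, phase = self._sway()
        ratio = symmetry_ratio(clip_movement(speed, phase))
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_asymmetric_trial_ratio_below_one(self):
        speed, phase = self._sway(rise=90, fall=135)
        ratio = symmetry_ratio(clip_movement(speed, phase))
        assert ratio < 0.8


class TestRatios:
    @pytest.mark.parametrize("clip,expected", [
        (MovementClipping(0, 60, 150), 60 / 90),
        (MovementClipping(0, 90, 150), 90 / 60),
    ])
    def test_symmetry_division_order(self, clip, expected):
        assert symmetry_ratio(clip) == pytest.approx(expected)

    @pytest.mark.parametrize("r,display,normalized", [
        (1.16, 1.16, 0.86),
        (1.0, 1.0, 1.0),
        (0.74, 0.74, 0.74),
    ])
    def test_report_ratio_reciprocal_convention(self, r, display, normalized):
        assert report_ratio(r) == (display, normalized)

    @given(st.floats(0.05, 20.0))
    def test_normalized_in_unit_interval_and_orientation_invariant(self, r):
        _, norm = report_ratio(r)
        _, norm_inv = report_ratio(1.0 / r)
        assert 0 < norm <= 1
        assert norm == pytest.approx(norm_inv, abs=0.01)

    def test_synchronicity_aligned_is_one(self):
        # hold segment of the hip path centered in the trunk clip
        path = make_path((0, 60), (1, 90), (2, 60), (3, 90), (0, 60))
        clip = MovementClipping(60, 180, 300)  # symmetric about m = 180
        assert synchronicity_ratio(path, clip) == pytest.approx(1.0)

    def test_synchronicity_orientation_trunk_early_below_one(self):
        """Spans of 40 frames before and 50 after the hold midpoint: the
        published convention divides the after-span by the before-span, so
        values < 1 mean the trunk moved before the hip."""
        path = make_path((0, 100), (2, 20), (0, 100))  # hold mid at 110
        clip = MovementClipping(70, 110, 160)  # 40 left, 50 right
        assert synchronicity_ratio(path, clip) == pytest.approx(50 / 40)
        early_clip = MovementClipping(40, 110, 130)
        assert synchronicity_ratio(path, early_clip) < 1

    def test_monotone_under_injected_shift(self):
        path = make_path((0, 60), (1, 90), (2, 60), (3, 90), (0, 60))
        base = synchronicity_ratio(path, MovementClipping(60, 180, 300))
        advanced = synchronicity_ratio(path, MovementClipping(30, 180, 270))
        assert advanced < base

    def test_no_hold_segment_is_incoordination(self):
        path = make_path((0, 50), (1, 50), (0, 50))
        with pytest.raises(IncoordinationError):
            synchronicity_ratio(path, MovementClipping(10, 75, 140))


class TestTransitionAnomalies:
    def _reference(self, *paths, n_states=3):
        # merge_gap=1: plain run-length visit counting for oracle clarity
        return build_reference_profile([np.asarray(p) for p in paths],
                                       n_states, min_segment=1, merge_gap=1)

    def test_reference_identical_path_clean(self):
        p = make_path((0, 50), (1, 40), (0, 30), (2, 40), (0, 50))
        ref = self._reference(p, p, p)
        assert detect_transition_anomalies(p, ref, visit_slack=0) == []

    def test_extra_hold_visit_flagged(self):
        """A path revisiting state 2 when correct executions visit it once
        raises one extra_transition flag on state 2 (strict counting)."""
        p = make_path((0, 50), (1, 40), (0, 30), (2, 40), (0, 50))
        ref = self._reference(p, p, p)
        extra = make_path((0, 50), (1, 40), (0, 30), (2, 40), (0, 40),
                          (2, 40), (0, 50))
        flags = detect_transition_anomalies(extra, ref, visit_slack=0)
        extra_flags = [f for f in flags if f.kind == "extra_transition"
                       and f.state == 2]
        assert len(extra_flags) == 1

    def test_missing_state_flagged(self):
        p = make_path((0, 50), (1, 40), (0, 30), (2, 40), (0, 50))
        ref = self._reference(p, p, p)
        missing = make_path((0, 50), (1, 40), (0, 160))
        kinds = {f.kind for f in detect_transition_anomalies(missing, ref,
                                                             visit_slack=0)}
        assert "missing_transition" in kinds

    def test_duration_anomalies_flagged(self):
        p = make_path((0, 50), (1, 40), (0, 30), (2, 40), (0, 50))
        ref = self._reference(p, p, p)
        long_hold = make_path((0, 50), (1, 40), (0, 30), (2, 90), (0, 50))
        kinds = {f.kind for f in detect_transition_anomalies(long_hold, ref,
                                                             visit_slack=0)}
        assert "elongated_state" in kinds

    def test_agrees_with_rle_oracle(self, rng):
        """Brute-force segment-count comparison on random paths matches the
        detector's visit-count flags exactly."""
        base_paths = [make_path((0, 30), (1, rng.integers(20, 40)),
                                (0, 20), (2, rng.integers(20, 40)), (0, 30))
                      for _ in range(5)]
        ref = self._reference(*base_paths)
        for _ in range(20):
            segs = []
            for s, l in [(0, 30), (1, 25), (0, 20), (2, 25), (0, 20)]:
                segs.append((s, int(l)))
                if rng.random() < 0.3:
                    segs.append((int(rng.integers(1, 3)), 25))
            path = make_path(*segs)
            flags = detect_transition_anomalies(path, ref, visit_slack=0)
            got = {(f.kind, f.state) for f in flags
                   if f.kind in ("extra_transition", "missing_transition")}
            # oracle: naive visit counting against the reference ranges
            counts = np.zeros(3, dtype=int)
            for s, _, _ in run_length_encode(path):
                counts[s] += 1
            expected = set()
            for s in range(3):
                if counts[s] > ref["visit_max"][s]:
                    expected.add(("extra_transition", s))
                elif counts[s] < ref["visit_min"][s]:
                    expected.add(("missing_transition", s))
            assert got == expected

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            detect_transition_anomalies(make_path((0, 10)), {})
        with pytest.raises(ValueError):
            build_reference_profile([make_path((0, 10))], 2)


class TestSmoothing:
    def test_short_runs_absorbed(self):
        p = make_path((0, 30), (1, 3), (0, 30), (1, 20), (0, 30))
        sm = smooth_path(p, min_segment=5)
        assert [s for s, _, _ in run_length_encode(sm)] == [0, 1, 0]

    def test_min_segment_one_is_identity(self):
        p = make_path((0, 5), (1, 1), (0, 5))
        assert np.array_equal(smooth_path(p, 1), p)


class TestErrorDirection:
    def _directional_features(self, obs):
        return FeatureSeries(feature_names=["lat_speed"], values=obs,
                             frame_rate=60.0, directional={"lat_speed": "lr"})

    def test_leftward_excess_labelled_left(self):
        model = GaussianHMM(1, [1.0], [[1.0]], [[0.0]], [[0.01]],
                            feature_names=["lat_speed"])
        obs = np.zeros((120, 1))
        obs[60:] = -1.0  # sustained leftward speed
        fs = self._directional_features(obs)
        trace = sliding_window_likelihood(model, obs, window_len=30, stride=30)
        labels = error_direction(model, trace, fs, threshold=-5.0)
        assert labels and all(lbl == "left" for _, lbl in labels)

    def test_unperturbed_sequence_has_no_labels(self):
        model = GaussianHMM(1, [1.0], [[1.0]], [[0.0]], [[0.01]],
                            feature_names=["lat_speed"])
        obs = np.random.default_rng(0).normal(0, 0.1, size=(120, 1))
        fs = self._directional_features(obs)
        trace = sliding_window_likelihood(model, obs, window_len=30, stride=30)
        assert error_direction(model, trace, fs, threshold=trace.min_value - 1) == []

    def test_model_without_directional_features_unsupported(self):
        fs = FeatureSeries(feature_names=["f0"], values=np.zeros((50, 1)),
                           frame_rate=60.0, directional={"f0": None})
        trace = sliding_window_likelihood(MODEL, np.zeros((50, 1)),
                                          window_len=10, stride=10)
        with pytest.raises(UnsupportedModelError):
            error_direction(MODEL, trace, fs, threshold=0.0)


class TestAggregation:
    THRESHOLDS = {"II": (-2.0, -4.0), "V": (-2.0, -4.0)}

    def test_rule_table(self):
        ok = {"II": -1.0, "V": -1.0}
        assert aggregate_outcome(ok, [], self.THRESHOLDS) == "good"
        one_flag = [AssessmentFlag("II", "extra_transition")]
        assert aggregate_outcome(ok, one_flag, self.THRESHOLDS) == "fair"
        assert aggregate_outcome(ok, one_flag * 2, self.THRESHOLDS) == "bad"
        low = {"II": -3.0, "V": -1.0}
        assert aggregate_outcome(low, [], self.THRESHOLDS) == "fair"
        assert aggregate_outcome({"II": -5.0, "V": -1.0}, [], self.THRESHOLDS) == "bad"

    def test_outcome_monotone_in_flags_and_likelihood(self):
        """Adding a flag or lowering a window likelihood never improves the
        outcome rank."""
        rank = {"bad": 0, "fair": 1, "good": 2}
        flags = [AssessmentFlag("II", "extra_transition")]
        for base_vals in ({"II": -1.0}, {"II": -3.0}, {"II": -5.0}):
            thr = {"II": (-2.0, -4.0)}
            for n in range(3):
                more = aggregate_outcome(base_vals, flags * (n + 1), thr)
                fewer = aggregate_outcome(base_vals, flags * n, thr)
                assert rank[more] <= rank[fewer]
            lower = {"II": base_vals["II"] - 1.0}
            assert rank[aggregate_outcome(lower, [], thr)] <= \
                rank[aggregate_outcome(base_vals, [], thr)]

    def test_missing_thresholds_rejected(self):
        with pytest.raises(Exception):
            aggregate_outcome({"II": -1.0}, [], {})


class TestLabelConsensus:
    def _labels(self, subject, trial, ratings_by_rater):
        out = []
        for rater, ratings in ratings_by_rater.items():
            for aspect, rating in ratings.items():
                out.append(TherapistLabel(subject, trial, aspect, rating, rater))
        return out

    def test_strict_majority_required_on_all_aspects(self):
        good = {"ROM": "good", "coordination": "good", "compensation": "good"}
        labels = self._labels("p1", "1", {"r1": good, "r2": good,
                                          "r3": {**good, "compensation": "fair"}})
        assert correct_trials(labels) == {("p1", "1")}
        labels += self._labels("p1", "2", {"r1": good, "r2": {**good, "ROM": "bad"},
                                           "r3": {**good, "ROM": "fair"}})
        assert ("p1", "2") not in correct_trials(labels)


class TestLosoAndClassify:
    def test_fold_bookkeeping(self, small_cohort, small_registries):
        subjects = {t.subject_id for t in small_cohort.trials}
        assert set(small_registries) == subjects
        for held_out, reg in small_registries.items():
            for entry in reg:
                trained_subjects = {t.split("/")[0]
                                    for t in entry.stats.training_trials}
                assert held_out not in trained_subjects
                assert len(trained_subjects) == len(subjects) - 1
        # folds overlap but differ
        t1 = set(small_registries["s1"]["II"].stats.training_trials)
        t2 = set(small_registries["s2"]["II"].stats.training_trials)
        assert t1 != t2 and t1 & t2

    def test_single_subject_fold_error(self, small_cohort_features, small_cohort):
        single = {k: v for k, v in small_cohort_features.items() if k[0] == "s1"}
        with pytest.raises(Exception):
            loso_train(single, small_cohort.labels, canonical_registry())

    def test_clean_trial_mostly_unflagged(self, small_cohort,
                                          small_cohort_features,
                                          small_registries):
        cfg = AssessConfig()
        clean = [t for t in small_cohort.trials if not t.truth.faults]
        flagged = 0
        for t in clean:
            a = classify_movement(small_registries[t.subject_id],
                                  small_cohort_features[(t.subject_id, t.trial_id)],
                                  cfg)
            flagged += bool(a.compensation_flags)
            assert a.outcome in ("good", "fair", "bad")
            assert a.symmetry is not None and a.symmetry > 0
        assert flagged / len(clean) <= 0.2

    def test_faulted_trials_flagged_and_downgraded(self, small_cohort,
                                                   small_cohort_features,
                                                   small_registries):
        cfg = AssessConfig()
        faulted = [t for t in small_cohort.trials if t.truth.faults]
        hits = 0
        for t in faulted:
            a = classify_movement(small_registries[t.subject_id],
                                  small_cohort_features[(t.subject_id, t.trial_id)],
                                  cfg)
            hits += bool(a.compensation_flags)
        assert hits / len(faulted) >= 0.8

    def test_empty_registry_rejected(self, small_cohort_features):
        fs = next(iter(small_cohort_features.values()))
        with pytest.raises(Exception):
            classify_movement(ModelRegistry(), fs)

    def test_registry_serialization_round_trip(self, small_registries, tmp_path):
        reg = small_registries["s1"]
        path = reg.save(tmp_path / "registry.json")
        back = ModelRegistry.load(path)
        assert set(back.entries) == set(reg.entries)
        for mid in reg.entries:
            a, b = reg[mid], back[mid]
            assert np.array_equal(a.model.means, b.model.means)
            assert a.stats.fair_threshold == b.stats.fair_threshold
            assert a.stats.reference_profile == b.stats.reference_profile
            assert a.role == b.role

    def test_duplicate_registry_id_rejected(self):
        reg = canonical_registry()
        with pytest.raises(Exception):
            reg.add(RegistryEntry(id="II", name="dup", n_states=3,
                                  feature_specs=canonical_registry()["II"].feature_specs))
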