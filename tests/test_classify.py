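"""Evaluation metrics, window-label post-processing and stage training."""

import numpy as np
import pytest

import chairrise as cr
from chairrise.classify import (
    STAGE_TRANSITION,
    ClassifierConfig,
    HierarchicalActivityClassifier,
    cross_validate,
    default_configs,
    evaluate,
    merge_short_segments,
    train_stage,
    window_truth_labels,
    windows_to_segments,
)
from chairrise.exceptions import InputError, ParameterError, TrainingError
from chairrise.features import FeatureSpec


class TestEvaluate:
    def test_worked_example(self):
        rep = cr.EvalReport.from_counts(tp=9, fp=1, fn=1)
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(0.9)

    def test_perfect_prediction(self):
        pred = ["SIT", "STAND", "SIT"]
        rep = evaluate(pred, pred, "SIT")
        assert rep.f1 == 1.0

    def test_zero_denominator_convention(self):
        rep = cr.EvalReport.from_counts(tp=0, fp=0, fn=5)
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            evaluate(["SIT"], ["SIT", "SIT"], "SIT")

    def test_class_swap_symmetry(self):
        pred = ["A", "A", "B", "B", "A"]
        truth = ["A", "B", "B", "A", "A"]
        ra, rb = evaluate(pred, truth, "A"), evaluate(pred, truth, "B")
        # in a two-class problem, A's false positives are B's false negatives
        assert ra.fp == rb.fn and ra.fn == rb.fp


class TestWindowsToSegments:
    def test_two_runs_two_segments(self):
        track = windows_to_segments(["SIT", "SIT", "STAND", "STAND"],
                                    step_s=0.5, window_s=1.0, smoothing_width=1)
        assert [s.label for s in track] == ["SIT", "STAND"]

    def test_mode_filter_removes_blip(self):
        track = windows_to_segments(["SIT", "STAND", "SIT"],
                                    step_s=0.5, window_s=1.0, smoothing_width=3)
        assert [s.label for s in track] == ["SIT"]

    def test_width_one_is_identity_on_runs(self):
        track = windows_to_segments(["SIT", "STAND", "SIT"],
                                    step_s=0.5, window_s=1.0, smoothing_width=1)
        assert [s.label for s in track] == ["SIT", "STAND", "SIT"]

    def test_even_width_rejected(self):
        with pytest.raises(ParameterError):
            windows_to_segments(["SIT"], 0.5, 1.0, smoothing_width=2)

    def test_boundaries_at_center_midpoints(self):
        track = windows_to_segments(["SIT", "STAND"], step_s=1.0, window_s=1.0,
                                    smoothing_width=1, t_first_center=0.5)
        assert track.segments[0] == cr.Segment(0.0, 1.0, "SIT")
        assert track.segments[1] == cr.Segment(1.0, 2.0, "STAND")


class TestMergeShortSegments:
    def test_short_blip_absorbed_into_longer_neighbour(self):
        track = cr.LabelTrack([(0, 2, "SIT_STAND"), (2, 2.2, "STAND_SIT"),
                               (2.2, 3.0, "STAND")])
        out = merge_short_segments(track, 0.5)
        assert [s.label for s in out] == ["SIT_STAND", "STAND"]
        assert out.segments[0].end == pytest.approx(2.2)

    def test_long_segments_untouched(self):
        track = cr.LabelTrack([(0, 2, "SIT"), (2, 4, "STAND")])
        assert merge_short_segments(track, 0.5) == track


class TestWindowTruthLabels:
    def test_majority_overlap(self):
        track = cr.LabelTrack([(0, 1.0, "SIT"), (1.0, 3.0, "SIT_STAND")])
        starts = np.array([0.0, 1.5])
        ends = np.array([1.2, 2.7])
        labels = window_truth_labels(track, starts, ends)
        assert list(labels) == ["SIT", "SIT_STAND"]

    def test_tie_breaks_toward_transition(self):
        track = cr.LabelTrack([(0, 1.0, "SIT"), (1.0, 2.0, "SIT_STAND")])
        labels = window_truth_labels(track, np.array([0.0]), np.array([2.0]))
        assert labels[0] == "SIT_STAND"

    def test_uncovered_time_counts_as_other(self):
        track = cr.LabelTrack([(10.0, 11.0, "SIT")])
        labels = window_truth_labels(track, np.array([0.0]), np.array([3.0]))
        assert labels[0] == "OTHER"


def _separable_features(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 0.3, size=(n // 2, 4)),
                   rng.normal(5.0, 0.3, size=(n // 2, 4))])
    y = np.array(["SIT_STAND"] * (n // 2) + ["STAND_SIT"] * (n // 2))
    return X, y


class TestTrainStage:
    @pytest.mark.parametrize("kind,arch", [("boosted_trees", ()), ("mlp", (16, 16))])
    def test_separable_data_fits_perfectly(self, kind, arch):
        X, y = _separable_features()
        cfg = ClassifierConfig(stage=STAGE_TRANSITION, model_kind=kind,
                               window_s=1.135, step_s=0.073, filter_fc=4.5,
                               feature_set=(FeatureSpec("rms", "acc"),),
                               hidden_layers=arch)
        model = train_stage(X, y, cfg, seed=0)
        rep = evaluate(model.predict(X), y, "SIT_STAND")
        assert rep.f1 == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = _separable_features(seed=3)
        cfg = default_configs()["transition"]
        a = train_stage(X, y, cfg, seed=7).predict(X)
        b = train_stage(X, y, cfg, seed=7).predict(X)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        y = np.array(["SIT"] * 10)
        with pytest.raises(TrainingError):
            train_stage(X, y, default_configs()["static"], seed=0)


@pytest.fixture(scope="module")
def fitted_small():
    """Hierarchy trained on three low-noise synthetic subjects."""
    sessions = [
        cr.generate_session(cr.SubjectProfile(
            seed=200 + i, fitness=0.4 + 0.2 * i, noise_sd=0.1,
            subject_id=f"T{i}"))
        for i in range(3)
    ]
    return HierarchicalActivityClassifier(sessions).fit(seed=0)


class TestHierarchy:
    def test_transition_labels_routed_through_transition_state(
            self, fitted_small, easy_bundle):
        from chairrise.classify import STAGE_STATE, stage_windows

        labels, starts, ends = fitted_small.predict_session(easy_bundle.imu)
        state_model = fitted_small.models[STAGE_STATE]
        X, s2, e2 = stage_windows(easy_bundle.imu, state_model.config)
        state_pred = state_model.predict(X)
        trans = np.isin(labels, ("SIT_STAND", "STAND_SIT"))
        assert np.all(state_pred[trans] == "transition")

    def test_five_crt_session_contains_both_transitions(
            self, fitted_small, easy_bundle):
        labels, _, _ = fitted_small.predict_session(easy_bundle.imu)
        assert "SIT_STAND" in labels and "STAND_SIT" in labels

    def test_pure_sitting_session_all_sit(self, fitted_small):
        profile = cr.SubjectProfile(seed=77, noise_sd=0.1)
        script = cr.SessionScript(
            cycles=(cr.CyclePlan(1.0, 0.5, 1.1, 0.5, 0.2),),
            pre=(("SIT", 10.0),), post=(("SIT", 3.0),))
        bundle = cr.generate_session(profile, script)
        sit = next(s for s in bundle.truth if s.label == "SIT")
        imu = bundle.imu.crop(sit.start + 0.5, sit.end - 0.5)
        labels, _, _ = fitted_small.predict_session(imu)
        assert set(labels) == {"SIT"}

    def test_too_short_recording_rejected(self, fitted_small, easy_bundle):
        short = easy_bundle.imu.crop(0.0, 1.0)   # < 2.511 s static window
        with pytest.raises(InputError):
            fitted_small.predict_session(short)

    def test_save_load_roundtrip(self, fitted_small, easy_bundle, tmp_path):
        path = tmp_path / "model.pkl"
        fitted_small.save(path)
        back = cr.ActivityClassifierResults.load(path)
        a, _, _ = fitted_small.predict_session(easy_bundle.imu)
        b, _, _ = back.predict_session(easy_bundle.imu)
        assert np.array_equal(a, b)

    def test_summary_lists_stages(self, fitted_small):
        text = fitted_small.summary()
        for stage in ("state", "static", "transition"):
            assert stage in text

    def test_missing_stage_rejected(self, fitted_small):
        with pytest.raises(InputError):
            cr.ActivityClassifierResults(
                models={"state": fitted_small.models["state"]})


def test_cross_validate_requires_enough_subjects(easy_bundle):
    with pytest.raises(ParameterError):
        cross_validate([easy_bundle], k=5)
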