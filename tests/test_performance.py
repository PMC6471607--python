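"""Temporal parameters, scoring bands and GRF phase segmentation."""

import numpy as np
import pytest

import chairrise as cr
from chairrise import (
    bias_correct_duration,
    compute_performance,
    detect_5crt,
    guralnik_score,
    segment_grf_phases,
)
from chairrise.exceptions import InputError, ParameterError
from conftest import make_track


class TestGuralnikScore:
    @pytest.mark.parametrize("duration,points", [
        (12.04, 3),      # population mean duration
        (11.19, 4),      # band edge
        (11.20, 3),
        (9.08, 4),       # fastest
        (16.27, 2),      # slowest
        (13.70, 2),
        (16.70, 1),
        (60.0, 1),
        (61.0, 0),
        ("incomplete", 0),
    ])
    def test_band_lookup(self, duration, points):
        assert guralnik_score(duration) == points

    def test_rounding_closes_band_gaps(self):
        # values inside the printed 0.01 s gaps still score
        assert guralnik_score(11.194) == 4
        assert guralnik_score(11.196) == 3

    def test_monotone_step_function_with_five_plateaus(self):
        grid = np.round(np.arange(0.01, 100.0, 0.01), 2)
        scores = np.array([guralnik_score(d) for d in grid])
        assert np.all(np.diff(scores) <= 0)
        assert set(scores) == {0, 1, 2, 3, 4}
        # exactly 5 plateaus -> 4 downward steps
        assert int(np.sum(np.diff(scores) != 0)) == 4

    def test_non_positive_duration_rejected(self):
        with pytest.raises(InputError):
            guralnik_score(0.0)


class TestBiasCorrection:
    def test_intercept_maps_to_zero(self):
        assert bias_correct_duration(1.96) == pytest.approx(0.0)

    def test_identity_coefficients(self):
        assert bias_correct_duration(12.3, slope=1.0, intercept=0.0) == 12.3

    def test_default_coefficients(self):
        assert bias_correct_duration(12.784) == pytest.approx(12.0, abs=1e-9)

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            bias_correct_duration(10.0, slope=0.0)


class TestComputePerformance:
    def test_uniform_test_arithmetic(self):
        track = make_track(5, rise=1.0, descent=1.0, stand=0.0, sit=0.0)
        rep = compute_performance(detect_5crt(track)[0])
        assert rep.total_duration_s == pytest.approx(9.0)   # 5 rises + 4 descents
        assert rep.cycle_durations == pytest.approx((2.0,) * 5)
        assert rep.fastest_cycle == 1                        # earliest tie-break
        assert rep.average_rise_s == pytest.approx(1.0)
        assert rep.average_descent_s == pytest.approx(1.0)
        assert len(rep.descent_durations) == 4

    def test_hold_makes_cycle_slowest(self):
        segs = []
        t = 0.0
        for i in range(5):
            segs.append((t, t + 1.0, "SIT_STAND")); t += 1.0
            if i == 2:
                segs.append((t, t + 2.0, "STAND")); t += 2.0
            if i < 4 or True:
                segs.append((t, t + 1.0, "STAND_SIT")); t += 1.0
        track = cr.LabelTrack(segs)
        rep = compute_performance(detect_5crt(track)[0])
        assert rep.slowest_cycle == 3

    def test_truncated_fifth_cycle_flagged(self):
        track = make_track(5, final_descent=False)
        rep = compute_performance(detect_5crt(track)[0])
        assert rep.cycle5_truncated
        assert rep.final_descent_s is None

    def test_segment_durations_sum_to_total(self, easy_bundle):
        test = detect_5crt(easy_bundle.truth)[0]
        rep = compute_performance(test)
        inside = sum(min(s.end, test.end) - max(s.start, test.start)
                     for s in test.segments
                     if s.start < test.end and s.end > test.start)
        assert inside == pytest.approx(rep.total_duration_s, abs=1e-9)

    def test_truth_track_recovers_scripted_durations(self, easy_bundle):
        test = detect_5crt(easy_bundle.truth)[0]
        rep = compute_performance(test)
        assert rep.total_duration_s == pytest.approx(easy_bundle.stopwatch_5crt, abs=1e-9)
        true_rises = [s.duration for s in easy_bundle.truth if s.label == "SIT_STAND"]
        assert rep.rise_durations == pytest.approx(tuple(true_rises), abs=1e-9)


class TestGrfPhases:
    def test_phase_recovery_on_noisefree_trace(self, noisefree_bundle):
        b = noisefree_bundle
        test = detect_5crt(b.truth)[0]
        ann = segment_grf_phases(b.force, test)
        assert len(ann) == 5
        for a, truth in zip(ann, b.meta["rise_phases"]):
            assert a.ok
            assert a.seat_off_t == pytest.approx(truth["seat_off_t"], abs=0.05)
            assert a.full_stand_t == pytest.approx(truth["full_stand_t"], abs=0.05)
            assert a.overshoot_N == pytest.approx(truth["overshoot_N"], rel=0.02)
            assert a.seat_off_t < a.peak_force_t < a.full_stand_t

    def test_programmed_overshoot_recovered(self):
        profile = cr.SubjectProfile(body_mass=79.6, fitness=(0.3 - 0.05) / 0.30,
                                    noise_sd=0.0, seed=4)
        assert profile.overshoot_frac == pytest.approx(0.3)
        b = cr.generate_session(profile)
        bw = 79.6 * 9.81
        test = detect_5crt(b.truth)[0]
        ann = segment_grf_phases(b.force, test)
        programmed = [ph["overshoot_N"] for ph in b.meta["rise_phases"]]
        for a, po in zip(ann, programmed):
            assert a.peak_force_N == pytest.approx(bw + po, rel=0.02)

    def test_constant_trace_yields_no_cycles(self):
        n = 2000
        rec = cr.ForcePlateRecording(
            t=np.arange(n) / 200.0, f_v=np.full(n, 300.0), f_ml=np.zeros(n),
            f_ap=np.zeros(n), body_weight=780.0, resting_weight=270.0)
        assert segment_grf_phases(rec, None) == []

    def test_two_rises_annotated_in_order(self):
        profile = cr.SubjectProfile(seed=9, fitness=0.5, noise_sd=0.0)
        script = cr.SessionScript(
            cycles=tuple(cr.CyclePlan(1.2, 0.6, 1.3, 0.5, 0.2) for _ in range(2)),
            pre=(("SIT", 3.0),), post=(("SIT", 3.0),))
        b = cr.generate_session(profile, script)
        ann = segment_grf_phases(b.force, None)
        assert len(ann) == 2
        assert all(a.ok for a in ann)
        assert ann[0].seat_off_t < ann[1].seat_off_t

    def test_weights_estimated_from_static_segments(self, noisefree_bundle):
        b = noisefree_bundle
        from dataclasses import replace

        force = replace(b.force, body_weight=None, resting_weight=None)
        test = detect_5crt(b.truth)[0]
        ann = segment_grf_phases(force, test)
        assert sum(a.ok for a in ann) >= 4
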