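"""Synthetic session generator: determinism, truth agreement, morphology."""

import numpy as np
import pytest


from chairrise import (
    SessionScript,
    SubjectProfile,
    corrupt_session,
    detect_5crt,
    generate_cohort,
    generate_session,
    guralnik_score,
)
from chairrise.exceptions import InputError, ParameterError


class TestDeterminism:
    def test_same_profile_bit_identical(self):
        a = generate_session(SubjectProfile(seed=9))
        b = generate_session(SubjectProfile(seed=9))
        np.testing.assert_array_equal(a.imu.acc_v, b.imu.acc_v)
        np.testing.assert_array_equal(a.force.f_v, b.force.f_v)
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_session(SubjectProfile(seed=1))
        b = generate_session(SubjectProfile(seed=2))
        assert not np.array_equal(a.imu.acc_v, b.imu.acc_v)


class TestScriptTruthAgreement:
    def test_programmed_rise_durations(self):
        profile = SubjectProfile(seed=5)
        script = SessionScript.from_profile(profile)
        bundle = generate_session(profile, script)
        rises = [s for s in bundle.truth if s.label == "SIT_STAND"]
        for seg, plan in zip(rises, script.cycles):
            assert seg.duration == pytest.approx(plan.rise_s, abs=0.01)

    def test_stopwatch_is_first_rise_to_fifth_rise_end(self):
        bundle = generate_session(SubjectProfile(seed=6))
        rises = [s for s in bundle.truth if s.label == "SIT_STAND"]
        assert bundle.stopwatch_5crt == pytest.approx(rises[-1].end - rises[0].start)

    def test_vertical_acc_at_rest_near_gravity(self):
        bundle = generate_session(SubjectProfile(seed=3, noise_sd=0.0))
        stand = next(s for s in bundle.truth if s.label == "STAND")
        m = (bundle.imu.t >= stand.start) & (bundle.imu.t < stand.end)
        assert np.median(bundle.imu.acc_v[m]) == pytest.approx(9.81, abs=0.05)


class TestMorphology:
    def test_programmed_overshoot(self):
        # fitness chosen so the nominal overshoot fraction is 0.3
        profile = SubjectProfile(body_mass=79.6, fitness=(0.30 - 0.05) / 0.30,
                                 noise_sd=0.0, seed=21)
        bundle = generate_session(profile)
        bw = 79.6 * 9.81
        assert bundle.force.body_weight == pytest.approx(bw)
        for seg, truth in zip(
                (s for s in bundle.truth if s.label == "SIT_STAND"),
                bundle.meta["rise_phases"]):
            m = (bundle.force.t >= seg.start) & (bundle.force.t < seg.end)
            peak = bundle.force.f_v[m].max()
            assert peak == pytest.approx(truth["peak_N"], rel=0.02)
            assert truth["peak_N"] - bw == pytest.approx(
                truth["overshoot_N"], abs=1e-9)

    def test_fit_subject_larger_force_range_unfit_more_sway(self):
        fit = generate_session(SubjectProfile(seed=31, fitness=0.9, noise_sd=0.0))
        unfit = generate_session(SubjectProfile(seed=31, fitness=0.2, noise_sd=0.0))

        def force_range(b):
            return float(np.ptp(b.force.f_v) / b.force.body_weight)

        def ml_sway_sd(b):
            stand = next(s for s in b.truth if s.label == "STAND")
            m = (b.imu.t >= stand.start) & (b.imu.t < stand.end)
            return float(np.std(b.imu.acc_ml[m]))

        assert force_range(fit) > force_range(unfit)
        assert ml_sway_sd(unfit) > ml_sway_sd(fit)

    def test_sitting_baseline_at_resting_weight(self):
        b = generate_session(SubjectProfile(seed=8, noise_sd=0.0))
        sit = next(s for s in b.truth if s.label == "SIT")
        m = (b.force.t >= sit.start) & (b.force.t < sit.end)
        assert np.median(b.force.f_v[m]) == pytest.approx(
            b.force.resting_weight, rel=1e-6)


class TestCohort:
    def test_cohort_duration_distribution(self):
        bundles = generate_cohort(20, seed=7)
        durations = [b.stopwatch_5crt for b in bundles]
        assert len(bundles) == 20
        assert min(durations) >= 8.0 and max(durations) <= 18.0
        assert 10.0 <= np.mean(durations) <= 14.0
        # spans at least the 4-, 3- and 2-point scoring bands
        assert {4, 3, 2} <= {guralnik_score(d) for d in durations}

    def test_single_subject(self):
        assert len(generate_cohort(1, seed=0)) == 1

    def test_seeds_give_different_cohorts(self):
        a = generate_cohort(3, seed=1)
        b = generate_cohort(3, seed=2)
        assert [x.stopwatch_5crt for x in a] != [x.stopwatch_5crt for x in b]

    def test_invalid_size_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(0)


class TestCorruption:
    @pytest.mark.parametrize("mode", ["interrupt_cycle", "inject_dynamic", "truncate"])
    def test_corrupted_sessions_not_detected(self, easy_bundle, mode):
        out = corrupt_session(easy_bundle, mode)
        assert detect_5crt(out.truth) == []
        assert out.stopwatch_5crt is None

    def test_unknown_mode_rejected(self, easy_bundle):
        with pytest.raises(ParameterError):
            corrupt_session(easy_bundle, "melt")

    def test_requires_full_test(self, easy_bundle):
        once = corrupt_session(easy_bundle, "interrupt_cycle")
        with pytest.raises(InputError):
            corrupt_session(once, "interrupt_cycle")


def test_intra_subject_similarity_exceeds_inter_subject():
    """Cycles of one subject resemble each other more than cycles of
    different subjects (time-normalized vertical force)."""
    from chairrise.patterns import normalized_xcorr, time_normalize

    bundles = generate_cohort(6, seed=13)

    def cycle_waveforms(b):
        out = []
        rises = [s for s in b.truth if s.label == "SIT_STAND"]
        descents = [s for s in b.truth if s.label == "STAND_SIT"]
        for r, d in zip(rises, descents):
            m = (b.force.t >= r.start) & (b.force.t < d.end)
            out.append(time_normalize(b.force.f_v[m], 250))
        return out

    waves = [cycle_waveforms(b) for b in bundles]
    intra = [normalized_xcorr(w[0], w[j], 0.2)
             for w in waves for j in range(1, len(w))]
    inter = [normalized_xcorr(waves[i][0], waves[j][0], 0.2)
             for i in range(len(waves)) for j in range(i + 1, len(waves))]
    assert np.mean(intra) > np.mean(inter)
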