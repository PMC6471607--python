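"""Similarity, time normalization and method-agreement analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chairrise as cr
from chairrise import (
    accel_magnitude,
    agreement,
    interpret_correlation,
    normalized_xcorr,
    time_normalize,
    variability_stats,
)
from chairrise.exceptions import InputError, ParameterError


class TestNormalizedXcorr:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=300)
        assert normalized_xcorr(s, s) == pytest.approx(1.0)

    def test_quarter_period_shift_recovered(self):
        t = np.arange(400) / 100.0
        s1 = np.sin(2 * np.pi * 1.0 * t)
        s2 = np.cos(2 * np.pi * 1.0 * t)
        assert normalized_xcorr(s1, s2, max_lag_fraction=0.5) == pytest.approx(1.0, abs=1e-3)

    def test_negated_signal_at_zero_lag(self):
        s = np.sin(np.linspace(0, 3, 200))
        assert normalized_xcorr(s, -s, max_lag_fraction=0.0) == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(InputError):
            normalized_xcorr(np.ones(50), np.arange(50.0))

    @given(alpha=st.floats(0.1, 20.0), beta=st.floats(-50.0, 50.0),
           seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_affine_amplitude_invariance(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=120)
        b = rng.normal(size=120)
        r0 = normalized_xcorr(a, b, 0.2)
        r1 = normalized_xcorr(a, alpha * b + beta, 0.2)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestTimeNormalize:
    def test_constant_stays_constant(self):
        out = time_normalize(np.full(37, 2.5), 100)
        np.testing.assert_allclose(out, 2.5)

    def test_ramp_endpoints_preserved(self):
        out = time_normalize(np.linspace(0, 1, 33), 50)
        assert out[0] == 0.0 and out[-1] == 1.0
        np.testing.assert_allclose(out, np.linspace(0, 1, 50), atol=1e-12)

    def test_stretched_cycle_similarity(self):
        t = np.linspace(0, 1, 200)
        cycle = np.sin(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t)
        stretched = np.interp(np.linspace(0, 1, 400), t, cycle)
        a = time_normalize(cycle, 250)
        b = time_normalize(stretched, 250)
        assert normalized_xcorr(a, b, 0.1) >= 0.999

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            time_normalize(np.arange(10.0), 1)


class TestAccelMagnitude:
    def test_rest_goes_to_zero(self):
        n = 400
        z = np.zeros(n)
        rec = cr.ImuRecording(t=np.arange(n) / 100.0, acc_v=np.full(n, 9.81),
                              acc_ml=z.copy(), acc_ap=z.copy(), gyr_v=z.copy(),
                              gyr_ml=z.copy(), gyr_ap=z.copy())
        np.testing.assert_allclose(accel_magnitude(rec), 0.0, atol=1e-9)

    def test_pythagorean_magnitude(self):
        n = 400
        z = np.zeros(n)
        # rest for gravity estimation, then a (3, 4, 0) excursion
        acc_v = np.full(n, 9.81); acc_v[300:320] += 3.0
        acc_ml = z.copy(); acc_ml[300:320] += 4.0
        rec = cr.ImuRecording(t=np.arange(n) / 100.0, acc_v=acc_v, acc_ml=acc_ml,
                              acc_ap=z.copy(), gyr_v=z.copy(), gyr_ml=z.copy(),
                              gyr_ap=z.copy())
        mag = accel_magnitude(rec)
        np.testing.assert_allclose(mag[305:315], 5.0, atol=1e-6)
        assert np.all(mag >= 0)


class TestAgreement:
    def test_exact_linear_relation(self):
        x = np.array([10.0, 11.0, 13.0, 14.5, 16.0])
        res = agreement(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_bland_altman_hand_example(self):
        res = agreement([10.0, 12.0, 14.0], [9.0, 12.0, 15.0])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)

    def test_identical_methods_zero_width(self):
        x = np.array([9.0, 12.0, 15.0, 11.0])
        res = agreement(x, x)
        assert res.mean_diff == 0.0
        assert res.loa_high - res.loa_low == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            agreement([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_recovers_known_relation_within_2se(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(9.0, 17.0, size=20)
        y = 0.902 * x + 1.96 + rng.normal(0.0, 0.5, size=20)
        res = agreement(x, y)
        assert abs(res.slope - 0.902) <= 2 * res.slope_se
        assert abs(res.intercept - 1.96) <= 2 * res.intercept_se
        assert res.significant(0.005)

    def test_summary_mentions_key_quantities(self):
        res = agreement([10.0, 12.0, 14.0], [9.0, 12.0, 15.0])
        text = res.summary()
        assert "limits of agreement" in text
        assert "Pearson" in text


class TestInterpretation:
    @pytest.mark.parametrize("r,label", [
        (0.94, "very high"), (0.88, "high"), (0.6, "moderate"),
        (0.4, "low"), (0.29, "negligible"), (-0.95, "very high"),
    ])
    def test_rule_of_thumb_bands(self, r, label):
        assert interpret_correlation(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            interpret_correlation(1.2)


class TestVariabilityStats:
    def test_basic_example(self):
        out = variability_stats([0.8, 0.9, 1.0])
        assert out["mean"] == pytest.approx(0.9)
        assert out["range"] == pytest.approx(0.2)
        assert out["median"] == pytest.approx(0.9)

    def test_single_value_sd_zero(self):
        assert variability_stats([0.7])["sd"] == 0.0

    def test_permutation_invariance(self):
        a = variability_stats([0.7, 0.95, 0.85, 0.8])
        b = variability_stats([0.85, 0.7, 0.8, 0.95])
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            variability_stats([])
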