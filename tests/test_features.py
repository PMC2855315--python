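"""Kinetic parameter extraction, ratio features and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hedonose as hn
from hedonose.simulate import _waveform
from conftest import make_measurement, make_trace


def dense_grid_params(times, values, oversample=10):
    """Brute-force oracle: same definitions on a 10x oversampled signal."""
    dense_t = np.linspace(times[0], times[-1], oversample * (len(times) - 1) + 1)
    dense_v = np.interp(dense_t, times, values)
    peak = int(np.argmax(dense_v))
    max_value = dense_v[peak]
    half = max_value / 2.0
    rise_idx = int(np.argmax(dense_v[: peak + 1] >= half))
    after = dense_v[peak:] <= half
    after[0] = False
    decay_idx = peak + int(np.argmax(after)) if after.any() else len(dense_t) - 1
    return max_value, dense_t[peak], dense_t[rise_idx], dense_t[decay_idx]


class TestSensorParams:
    def test_piecewise_linear_closed_form(self):
        # rise 0->10 over [0,10], decay 10->0 over [10,20]:
        # max 10 at t=10, half-max crossings at t=5 and t=15
        t = np.arange(21.0)
        v = np.where(t <= 10, t, 20.0 - t)
        p = hn.extract_sensor_params(make_trace(t, v), baseline_window=0.0)
        assert p.as_tuple() == pytest.approx((10.0, 10.0, 5.0, 15.0))

    def test_all_constant_trace_degenerate(self):
        p = hn.extract_sensor_params(make_trace([0, 1, 2, 3], [2.0] * 4))
        assert p.max_value == 0.0
        assert p.latency_to_max == p.t_half_rise == p.t_half_decay == 0.0
        assert "degenerate" in p.flags

    def test_never_decaying_signal_flagged_with_last_timestamp(self):
        t = np.arange(10.0)
        v = np.minimum(t, 5.0)  # rises then plateaus above half max
        p = hn.extract_sensor_params(make_trace(t, v), baseline_window=0.0)
        assert p.t_half_decay == 9.0
        assert "no_decay_half" in p.flags

    def test_double_exponential_matches_analytic_half_rise(self):
        # value(t) = A(1-exp(-t/tau_r)) during injection; the first crossing
        # of half the observed peak is -tau_r*ln(1 - 0.5*peak_fraction)
        tau_r, t_inj = 10.0, 30.0
        t = np.arange(0.0, 301.0)
        v = _waveform(t, 1.0, tau_r, 40.0, t_inj)
        peak_fraction = 1.0 - np.exp(-t_inj / tau_r)
        analytic_rise = -tau_r * np.log(1.0 - 0.5 * peak_fraction)
        analytic_decay = t_inj + 40.0 * np.log(2.0)
        p = hn.extract_sensor_params(make_trace(t, v), baseline_window=0.0)
        assert p.t_half_rise == pytest.approx(analytic_rise, abs=1.0)
        assert p.t_half_decay == pytest.approx(analytic_decay, abs=1.0)
        assert p.latency_to_max == pytest.approx(t_inj, abs=1.0)

    @pytest.mark.parametrize("tau_r,tau_d", [(4.0, 15.0), (10.0, 40.0), (12.0, 60.0)])
    def test_agrees_with_dense_grid_oracle(self, tau_r, tau_d):
        t = np.arange(0.0, 301.0)
        v = _waveform(t, 2.0, tau_r, tau_d, 30.0)
        p = hn.extract_sensor_params(make_trace(t, v), baseline_window=0.0)
        o_max, o_peak, o_rise, o_decay = dense_grid_params(t, v)
        dt = 1.0  # coarse-grid sample interval
        assert p.max_value == pytest.approx(o_max, rel=1e-6)
        assert p.latency_to_max == pytest.approx(o_peak, abs=dt)
        assert p.t_half_rise == pytest.approx(o_rise, abs=dt)
        assert p.t_half_decay == pytest.approx(o_decay, abs=dt)


class TestMaxRatios:
    def test_all_ones_gives_all_ones(self):
        np.testing.assert_allclose(hn.max_ratios(np.ones(8)), np.ones(28))

    def test_count_is_8_choose_2(self):
        assert len(hn.max_ratios(np.arange(1.0, 9.0))) == 28

    def test_matches_pair_enumeration_oracle(self):
        m = np.array([2.0, 1, 1, 1, 1, 1, 1, 1])
        eps = 1e-9
        oracle = [
            (m[i] + eps) / (m[j] + eps)
            for i in range(8) for j in range(i + 1, 8)
        ]
        out = hn.max_ratios(m)
        np.testing.assert_allclose(out, oracle)
        np.testing.assert_allclose(out[:7], 2.0, rtol=1e-6)
        np.testing.assert_allclose(out[7:], 1.0, rtol=1e-6)

    def test_epsilon_guards_zero_division(self):
        out = hn.max_ratios(np.zeros(8))
        assert np.all(np.isfinite(out)) and np.all(out > 0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="8 maxima"):
            hn.max_ratios(np.ones(7))


class TestExtractFeatures:
    def test_feature_vector_has_canonical_length_and_names(self):
        vec = hn.extract_features(make_measurement())
        assert len(vec) == 120
        assert len(hn.FEATURE_NAMES) == 120

    def test_deterministic(self):
        a = hn.extract_features(make_measurement()).values
        b = hn.extract_features(make_measurement()).values
        np.testing.assert_array_equal(a, b)

    def test_common_scaling_moves_maxima_not_ratios_or_times(self):
        m1 = make_measurement()
        scaled = hn.Measurement(
            odorant_id=m1.odorant_id, repetition=m1.repetition,
            traces=[
                hn.SensorTrace(t.sensor_id, t.times, 3.0 * t.values)
                for t in m1.traces
            ],
        )
        v1 = hn.extract_features(m1).values
        v3 = hn.extract_features(scaled).values
        kin = np.arange(64).reshape(16, 4)
        np.testing.assert_allclose(v3[kin[:, 0]], 3.0 * v1[kin[:, 0]], rtol=1e-9)
        for col in (1, 2, 3):  # latency and half-max times unchanged
            np.testing.assert_allclose(v3[kin[:, col]], v1[kin[:, col]], atol=1e-9)
        np.testing.assert_allclose(v3[64:], v1[64:], rtol=1e-6)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_ratio_block_invariant_to_any_common_scale(self, scale):
        m1 = make_measurement()
        scaled = hn.Measurement(
            odorant_id="x", repetition=1,
            traces=[
                hn.SensorTrace(t.sensor_id, t.times, scale * t.values)
                for t in m1.traces
            ],
        )
        np.testing.assert_allclose(
            hn.extract_features(scaled).values[64:],
            hn.extract_features(m1).values[64:],
            rtol=1e-5,
        )


class TestNormalization:
    def test_columns_standardized_then_rows_unit_norm(self):
        rng = np.random.default_rng(0)
        matrix = hn.FeatureMatrix(
            [f"o{i}:1" for i in range(30)], [f"o{i}" for i in range(30)],
            rng.normal(2.0, 3.0, size=(30, 120)),
        )
        normalizer = hn.Normalizer()
        cols = normalizer.fit(matrix).column_normalize(matrix)
        assert cols.state == "column_normalized"
        np.testing.assert_allclose(cols.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(cols.values.std(axis=0), 1.0, atol=1e-12)
        full = normalizer.transform(matrix)
        assert full.state == "fully_normalized"
        np.testing.assert_allclose(
            np.linalg.norm(full.values, axis=1), 1.0, atol=1e-12
        )

    def test_constant_columns_map_to_zero(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 120))
        values[:, 5] = 7.0
        matrix = hn.FeatureMatrix(
            [f"o{i}:1" for i in range(10)], [f"o{i}" for i in range(10)], values
        )
        out = hn.normalize(matrix)
        np.testing.assert_array_equal(out.values[:, 5], 0.0)

    def test_single_row_rejected(self):
        matrix = hn.FeatureMatrix(["a:1"], ["a"], np.ones((1, 120)))
        with pytest.raises(ValueError, match="fewer than 2"):
            hn.normalize(matrix)

    def test_gain_noise_cancelled_on_balanced_patterns(self):
        # rows are c_i * pattern_k for two opposite patterns (+B and -B), so
        # every column has exactly zero mean; after column standardization
        # rows stay proportional to their pattern and row normalization then
        # makes same-pattern rows identical -- the concentration-removal
        # property the pipeline relies on
        rng = np.random.default_rng(2)
        base = rng.normal(size=120)
        gains = [1.0, 1.7, 2.4]
        rows = [c * base for c in gains] + [-c * base for c in gains]
        matrix = hn.FeatureMatrix(
            [f"s{i}:1" for i in range(6)],
            ["plus"] * 3 + ["minus"] * 3,
            np.array(rows),
        )
        out = hn.normalize(matrix).values
        for i in (1, 2):
            np.testing.assert_allclose(out[i], out[0], atol=1e-9)
            np.testing.assert_allclose(out[3 + i], out[3], atol=1e-9)
        np.testing.assert_allclose(out[0], -out[3], atol=1e-9)

    def test_frozen_statistics_reused_for_novel_data(self):
        rng = np.random.default_rng(3)
        train = hn.FeatureMatrix(
            [f"a{i}:1" for i in range(20)], [f"a{i}" for i in range(20)],
            rng.normal(size=(20, 120)),
        )
        novel = hn.FeatureMatrix(
            [f"b{i}:1" for i in range(5)], [f"b{i}" for i in range(5)],
            rng.normal(loc=5.0, size=(5, 120)),
        )
        normalizer = hn.Normalizer().fit(train)
        out = normalizer.transform(novel)
        # novel data standardized with train statistics, not its own
        recompute = (novel.values - train.values.mean(0)) / train.values.std(0)
        recompute /= np.linalg.norm(recompute, axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, recompute, atol=1e-12)
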