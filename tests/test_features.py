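"""Feature transforms: differencing, circular windows, normalization, streaming."""

import cmath
import math

import numpy as np
import pytest

from warmgait import quaternions as quat
from warmgait.features import (
    FeatureTable,
    NormalizationStats,
    RealSeries,
    StreamingFeatureExtractor,
    UQTSTrial,
    build_features,
    local_circular_mean,
    local_circular_sd,
    normalize_features,
    qdts,
    qfdts,
)

from conftest import random_unit_quats


def make_trial(quats, dt=0.01, labels=None):
    n = len(quats)
    return UQTSTrial(times=np.arange(n) * dt, quaternions=np.asarray(quats), labels=labels)


def series(values):
    values = np.asarray(values, dtype=float)
    return RealSeries(times=np.arange(values.size) * 0.01, values=values)


# --- independent brute-force oracles (plain Python, no shared code) ---------


def circ_mean_oracle(vals, h):
    out = []
    for ell in range(len(vals)):
        w = vals[max(ell - h, 0) : ell + 1]
        out.append(math.atan2(sum(math.sin(x) for x in w), sum(math.cos(x) for x in w)))
    return out


def circ_sd_oracle(vals, h):
    out = []
    for ell in range(len(vals)):
        w = vals[max(ell - h, 0) : ell + 1]
        if len(w) == 1:
            out.append(0.0)  # R̄ of a single angle is exactly 1
            continue
        rbar = abs(sum(cmath.exp(1j * x) for x in w) / len(w))
        out.append(math.sqrt(-2.0 * math.log(min(rbar, 1.0))) if rbar > 0 else math.inf)
    return out


# --- trial container --------------------------------------------------------


class TestUQTSTrial:
    def test_rejects_nonuniform_grid(self, rng):
        q = random_unit_quats(rng, 4)
        with pytest.raises(ValueError, match="uniform grid"):
            UQTSTrial(times=[0.0, 0.01, 0.03, 0.04], quaternions=q)

    def test_rejects_non_unit_quaternions(self):
        q = np.tile([0.9, 0.0, 0.0, 0.0], (3, 1))
        with pytest.raises(ValueError, match="unit-norm"):
            UQTSTrial(times=[0.0, 0.01, 0.02], quaternions=q)

    def test_rejects_bad_labels(self, rng):
        q = random_unit_quats(rng, 3)
        with pytest.raises(ValueError, match="binary"):
            UQTSTrial(times=[0, 0.01, 0.02], quaternions=q, labels=[0, 2, 1])


# --- finite differencing and distance series --------------------------------


class TestQfdts:
    def test_constant_trial_gives_identities(self):
        trial = make_trial(np.tile([0.5, 0.5, 0.5, 0.5], (6, 1)))
        out = qfdts(trial)
        assert out.n_samples == 5
        assert np.allclose(out.quaternions, quat.IDENTITY, atol=1e-12)

    def test_two_point_trial_matches_direct_composition(self, rng):
        a, b = random_unit_quats(rng, 2)
        out = qfdts(make_trial([a, b]))
        expected = quat.hamilton_product(quat.inverse(a), b)
        assert np.allclose(out.quaternions[0], expected, atol=1e-15)
        assert out.times[0] == pytest.approx(0.01)  # later endpoint

    def test_length_is_p_minus_one(self, rng):
        trial = make_trial(random_unit_quats(rng, 37))
        assert qfdts(trial).n_samples == 36

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="two samples"):
            qfdts(make_trial(random_unit_quats(rng, 1)))


class TestQdts:
    def test_constant_trial_is_all_zero(self):
        trial = make_trial(np.tile([1.0, 0, 0, 0], (8, 1)))
        assert np.all(qdts(trial).values == 0.0)

    def test_constant_rotation_rate_gives_constant_angle(self):
        theta = 0.3
        step = np.array([math.cos(theta / 2), 0, 0, math.sin(theta / 2)])
        q = [np.array([1.0, 0, 0, 0])]
        for _ in range(9):
            q.append(quat.hamilton_product(q[-1], step))
        d = qdts(make_trial(q)).values
        assert np.allclose(d, theta, atol=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        qs = random_unit_quats(rng, 30)
        d = qdts(make_trial(qs)).values
        for ell in range(29):
            a, b = qs[ell], qs[ell + 1]
            re = float(np.dot(a, b))
            assert d[ell] == pytest.approx(2 * math.acos(max(-1, min(1, re))), abs=1e-12)


# --- circular sliding windows ------------------------------------------------


class TestLocalCircularMean:
    def test_h0_returns_input_exactly(self, rng):
        d = series(rng.uniform(0, 2 * np.pi, 50))
        out = local_circular_mean(d, 0)
        assert np.array_equal(out.values, d.values)

    @pytest.mark.parametrize("h", [1, 3, 10])
    def test_constant_input_passthrough(self, h):
        out = local_circular_mean(series(np.full(20, 1.3)), h)
        assert np.allclose(out.values, 1.3, atol=1e-12)

    def test_two_angle_window_example(self):
        # window {0, π/2}: atan2(1, 1) = π/4
        out = local_circular_mean(series([0.0, math.pi / 2]), 1)
        assert out.values[1] == pytest.approx(math.pi / 4, abs=1e-15)

    def test_matches_bruteforce_oracle(self, rng):
        vals = rng.uniform(0.05, 3.0, 80).tolist()
        for h in (1, 4, 9):
            out = local_circular_mean(series(vals), h)
            assert np.allclose(out.values, circ_mean_oracle(vals, h), atol=1e-12)

    def test_tight_cluster_stays_in_window_hull(self, rng):
        """For angles within (−π/2, π/2) the circular mean behaves like an
        arithmetic mean: each output lies within its window's range."""
        vals = rng.uniform(-1.2, 1.2, 60)
        h = 5
        out = local_circular_mean(series(vals), h).values
        for ell in range(60):
            w = vals[max(ell - h, 0) : ell + 1]
            assert w.min() - 1e-12 <= out[ell] <= w.max() + 1e-12

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            local_circular_mean(series([0.1, 0.2]), -1)


class TestLocalCircularSD:
    def test_h0_is_all_zeros_exactly(self, rng):
        out = local_circular_sd(series(rng.uniform(0, 3, 30)), 0)
        assert np.all(out.values == 0.0)

    @pytest.mark.parametrize("h", [1, 5, 12])
    def test_constant_input_is_all_zeros(self, h):
        out = local_circular_sd(series(np.full(25, 0.7)), h)
        assert np.all(out.values == 0.0)

    def test_two_angle_window_example(self):
        # window {0, π/2}: R̄ = |(1 + i)/2| = √2/2, σ = sqrt(−2 ln(√2/2))
        out = local_circular_sd(series([0.0, math.pi / 2]), 1)
        expected = math.sqrt(-2 * math.log(math.sqrt(2) / 2))
        assert out.values[1] == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        vals = rng.uniform(0.05, 3.0, 80).tolist()
        for h in (1, 4, 9):
            out = local_circular_sd(series(vals), h)
            assert np.allclose(out.values, circ_sd_oracle(vals, h), atol=1e-12)

    def test_antipodal_window_capped_with_warning(self):
        vals = [0.5, 0.4, 0.0, math.pi]  # last window {0, π} has R̄ = 0
        with pytest.warns(RuntimeWarning, match="zero resultant"):
            out = local_circular_sd(series(vals), 1)
        finite_max = max(circ_sd_oracle(vals, 1)[:3])
        assert out.values[3] == pytest.approx(finite_max)

    def test_explicit_cap_used(self):
        with pytest.warns(RuntimeWarning):
            out = local_circular_sd(series([0.0, math.pi]), 1, cap=9.9)
        assert out.values[1] == 9.9


# --- feature assembly and normalization --------------------------------------


class TestBuildFeatures:
    def test_constant_trial_all_zero_features(self):
        trial = make_trial(np.tile([0.5, -0.5, 0.5, -0.5], (30, 1)), labels=np.zeros(30, int))
        table = build_features(trial, h=5)
        assert np.all(table.lm == 0.0) and np.all(table.lsd == 0.0)
        assert len(table) == 29

    def test_labels_align_to_later_timestamps(self, rng):
        labels = np.array([1] + [0] * 9)
        trial = make_trial(random_unit_quats(rng, 10), labels=labels)
        table = build_features(trial, h=2)
        assert np.array_equal(table.label, labels[1:])
        assert np.allclose(table.times, trial.times[1:])

    def test_output_lengths(self, rng):
        trial = make_trial(random_unit_quats(rng, 64))
        table = build_features(trial, h=7)
        assert len(table) == 63


class TestNormalizeFeatures:
    def test_self_normalization_zero_mean_unit_sd(self, rng):
        table = FeatureTable(
            times=np.arange(100) * 0.01,
            lm=rng.normal(2.0, 0.5, 100),
            lsd=rng.normal(0.1, 0.02, 100),
        )
        out, stats = normalize_features(table)
        assert out.lm.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.lm.std() == pytest.approx(1.0, abs=1e-9)
        assert out.lsd.std() == pytest.approx(1.0, abs=1e-9)

    def test_training_stats_applied_without_reestimation(self, rng):
        train = FeatureTable(
            times=np.arange(50) * 0.01, lm=rng.normal(size=50), lsd=rng.normal(size=50)
        )
        test = FeatureTable(
            times=np.arange(50) * 0.01,
            lm=rng.normal(3.0, 2.0, 50),
            lsd=rng.normal(3.0, 2.0, 50),
        )
        _, stats = normalize_features(train)
        out, _ = normalize_features(test, stats)
        assert abs(out.lm.mean()) > 0.5  # shifted: train stats, not per-table z-scores
        assert np.allclose(out.lm, (test.lm - stats.lm_center) / stats.lm_scale)

    def test_constant_column_rejected(self):
        table = FeatureTable(
            times=np.arange(10) * 0.01, lm=np.ones(10), lsd=np.arange(10.0)
        )
        with pytest.raises(ValueError, match="constant feature"):
            normalize_features(table)

    def test_zero_scale_stats_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            NormalizationStats(lm_center=0, lm_scale=0, lsd_center=0, lsd_scale=1)


# --- streaming ----------------------------------------------------------------


class TestStreaming:
    @pytest.mark.parametrize("h", [0, 1, 13, 50])
    def test_streaming_equals_batch(self, rng, h):
        qs = random_unit_quats(rng, 400)
        trial = make_trial(qs)
        batch = build_features(trial, h)
        ext = StreamingFeatureExtractor(h)
        lm, lsd = [], []
        for q, t in zip(qs, trial.times):
            out = ext.push(q, t)
            if out is not None:
                lm.append(out[0])
                lsd.append(out[1])
        assert np.array_equal(lm, batch.lm)
        assert np.array_equal(lsd, batch.lsd)

    def test_first_sample_yields_nothing(self, rng):
        ext = StreamingFeatureExtractor(5)
        assert ext.push(random_unit_quats(rng, 1)[0], 0.0) is None

    def test_second_sample_uses_truncated_window(self, rng):
        a, b = random_unit_quats(rng, 2)
        ext = StreamingFeatureExtractor(5)
        ext.push(a, 0.0)
        lm, lsd = ext.push(b, 0.01)
        d = float(quat.geodesic_distance(a, b))
        assert lm == pytest.approx(math.atan2(math.sin(d), math.cos(d)), abs=1e-15)
        assert lsd == 0.0  # single-angle window

    def test_out_of_order_timestamp_rejected(self, rng):
        a, b = random_unit_quats(rng, 2)
        ext = StreamingFeatureExtractor(2)
        ext.push(a, 0.0)
        with pytest.raises(ValueError, match="out-of-order"):
            ext.push(b, 0.0)
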