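import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatsync import (
    TooFewResponsesError,
    circular_variance,
    detect_bimodality,
    events_to_angles,
    rayleigh_test,
    resultant_length,
    segment_angles,
)
from beatsync.circular import AngleSeries, rayleigh_p


def brute_force_R(angles):
    """Independent oracle: explicit unit-vector summation."""
    x = sum(np.cos(a) for a in angles) / len(angles)
    y = sum(np.sin(a) for a in angles) / len(angles)
    return (x * x + y * y) ** 0.5


angle_sets = st.lists(
    st.floats(min_value=0.0, max_value=2 * np.pi - 1e-9), min_size=4, max_size=40
)


class TestAngles:
    def test_events_on_the_beat_map_to_zero(self):
        series = events_to_angles(np.array([0.48, 0.96, 1.44]), 480.0, 1)
        np.testing.assert_allclose(series.angles, 0.0, atol=1e-9)

    def test_midpoint_maps_to_pi(self):
        series = events_to_angles(np.array([0.24]), 480.0, 1)
        assert series.angles[0] == pytest.approx(np.pi)

    def test_matches_modular_arithmetic_oracle(self, rng):
        times = np.sort(rng.uniform(10, 100, size=15))
        ibi = 60000.0 / 124.0
        series = events_to_angles(times, ibi, 2)
        oracle = [2 * np.pi * ((t * 1000.0) % (2 * ibi)) / (2 * ibi) for t in times]
        np.testing.assert_allclose(series.angles, oracle, atol=1e-9)

    def test_translation_by_circle_multiple_is_invariant(self, rng):
        times = np.sort(rng.uniform(10, 50, size=12))
        ibi = 480.0
        a = events_to_angles(times, ibi, 1)
        b = events_to_angles(times + 3 * ibi / 1000.0, ibi, 1)
        assert resultant_length(a) == pytest.approx(resultant_length(b), abs=1e-9)

    def test_empty_events_rejected(self):
        with pytest.raises(TooFewResponsesError):
            events_to_angles(np.array([]), 480.0, 1)


class TestResultantAndVariance:
    def test_identical_angles_give_unit_resultant(self):
        assert resultant_length(np.full(7, 1.3)) == pytest.approx(1.0)
        assert circular_variance(np.full(7, 1.3)) == pytest.approx(0.0)

    def test_balanced_cross_gives_zero_resultant(self):
        cross = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert resultant_length(cross) == pytest.approx(0.0, abs=1e-12)
        assert circular_variance(cross) == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_angles(self):
        pair = np.array([0.0, np.pi / 2])
        assert resultant_length(pair) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert circular_variance(pair) == pytest.approx(1 - np.sqrt(2) / 2, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(angle_sets)
    def test_agrees_with_brute_force_oracle(self, angles):
        assert resultant_length(np.array(angles)) == pytest.approx(
            brute_force_R(angles), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(angle_sets, st.floats(min_value=0.0, max_value=2 * np.pi))
    def test_rotation_invariance(self, angles, shift):
        theta = np.asarray(angles)
        rotated = np.mod(theta + shift, 2 * np.pi)
        r0 = rayleigh_test(theta)
        r1 = rayleigh_test(rotated)
        assert r1.R == pytest.approx(r0.R, abs=1e-9)
        assert r1.z == pytest.approx(r0.z, abs=1e-9)
        assert r1.p == pytest.approx(r0.p, abs=1e-9)
        assert circular_variance(rotated) == pytest.approx(
            circular_variance(theta), abs=1e-9
        )


class TestRayleigh:
    def test_balanced_cross_is_maximally_uniform(self):
        result = rayleigh_test(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert result.R == pytest.approx(0.0, abs=1e-12)
        assert result.z == pytest.approx(0.0, abs=1e-12)
        # exp(sqrt(1 + 16 + 64) - 9) = exp(0) = 1 at n=4, R=0
        assert result.p == pytest.approx(1.0)

    def test_perfect_concentration(self):
        result = rayleigh_test(np.full(20, 0.7))
        assert result.R == pytest.approx(1.0)
        assert result.z == pytest.approx(20.0)
        # exp(sqrt(1 + 80 + 0) - 41) = e^-32
        assert result.p == pytest.approx(np.exp(-32), rel=1e-9)

    def test_z_equals_n_R_squared(self, rng):
        theta = rng.uniform(0, 2 * np.pi, size=25)
        result = rayleigh_test(theta)
        assert result.z == pytest.approx(result.n * result.R**2, abs=1e-12)

    def test_too_few_responses(self):
        with pytest.raises(TooFewResponsesError):
            rayleigh_test(np.array([0.1, 0.2, 0.3]))

    def test_type_one_error_calibrated(self):
        # 5000 uniform samples of n=30: rejection rate at alpha=.05
        rng = np.random.default_rng(12345)
        theta = rng.uniform(0, 2 * np.pi, size=(5000, 30))
        R = np.abs(np.mean(np.exp(1j * theta), axis=1))
        p = rayleigh_p(np.full(5000, 30), R)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        theta = rng.uniform(0, 2 * np.pi, size=30)
        ours = rayleigh_test(theta)
        z_pg, p_pg = pingouin.circ_rayleigh(theta)
        assert ours.z == pytest.approx(z_pg, abs=1e-9)
        assert ours.p == pytest.approx(p_pg, rel=1e-6)
        assert ours.R == pytest.approx(float(pingouin.circ_r(theta)), abs=1e-9)


class TestSegmentation:
    @pytest.mark.parametrize(
        "n,L,sizes",
        [
            (40, 1, [10, 10, 10, 10]),
            (42, 1, [11, 11, 10, 10]),
            (21, 2, [11, 10]),
        ],
    )
    def test_segment_sizes(self, n, L, sizes):
        series = AngleSeries(angles=np.linspace(0, 2 * np.pi, n, endpoint=False), circle_span_ms=480.0)
        segments = segment_angles(series, L)
        assert [len(s) for s in segments] == sizes
        # order-preserving and exhaustive
        np.testing.assert_array_equal(
            np.concatenate([s.angles for s in segments]), series.angles
        )

    def test_too_few_responses_for_segments(self):
        series = AngleSeries(angles=np.linspace(0, 1, 10), circle_span_ms=480.0)
        with pytest.raises(TooFewResponsesError):
            segment_angles(series, 1)  # 4 segments need >= 16


class TestBimodality:
    def test_antipodal_clusters_flagged(self, rng):
        theta = np.concatenate(
            [rng.normal(0, 0.1, 25), rng.normal(np.pi, 0.1, 25)]
        ) % (2 * np.pi)
        result = detect_bimodality(theta)
        assert result.bimodal is True
        assert result.R_doubled - result.R >= 0.2

    def test_single_cluster_not_flagged(self, rng):
        theta = rng.normal(1.0, 0.1, 40) % (2 * np.pi)
        assert detect_bimodality(theta).bimodal is False

    def test_uniform_false_flag_rate_bounded(self):
        rng = np.random.default_rng(99)
        flags = 0
        reps = 400
        for _ in range(reps):
            theta = rng.uniform(0, 2 * np.pi, size=50)
            if detect_bimodality(theta).bimodal:
                flags += 1
        assert flags / reps <= 0.05 + 0.02

    def test_small_samples_undetermined(self):
        assert detect_bimodality(np.linspace(0, 1, 5)).bimodal is None
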