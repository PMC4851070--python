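"""Component feature extractors against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.signal import lfilter

from signcomp.features import (
    ar_coefficients,
    axis_features,
    handshape_features,
    mav,
    orientation_features,
    rotation_features,
    slope_sign_changes,
    trajectory_features,
    waveform_length,
    zero_crossings,
)
from signcomp.preprocess import WindowingSpec


# -- brute-force oracles: plain python loops, no vectorisation ---------------

def mav_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def zc_oracle(x, thr):
    count = 0
    for a, b in zip(x[:-1], x[1:]):
        if a * b < 0 and abs(a - b) >= thr:
            count += 1
    return count


def ssc_oracle(x, thr):
    count = 0
    for i in range(1, len(x) - 1):
        prod = (x[i] - x[i - 1]) * (x[i] - x[i + 1])
        if prod >= thr and prod > 0:
            count += 1
    return count


def wl_oracle(x):
    return sum(abs(b - a) for a, b in zip(x[:-1], x[1:]))


def axis_oracle(stage):
    s = [list(ch) for ch in stage]
    n = len(s[0])
    for ch in s:
        m = sum(ch) / n
        for i in range(n):
            ch[i] -= m
    stds = [(sum(v * v for v in ch) / n) ** 0.5 for ch in s]
    snorm = sum(sum(v * v for v in ch) ** 0.5 for ch in s)
    out = list(stds)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        dot = sum(a * b for a, b in zip(s[i], s[j]))
        out.append(abs(dot) / snorm * (1 if dot > 0 else -1 if dot < 0 else 0))
    return np.array(out)


class TestScalarExamples:
    def test_mav_direct_case(self):
        assert mav([1, -1, 2, -2]) == pytest.approx(1.5)
        assert mav(np.zeros(10)) == 0.0

    def test_mav_homogeneity(self, rng):
        x = rng.normal(size=50)
        assert mav(-3.0 * x) == pytest.approx(3.0 * mav(x))

    def test_zc_enumerated_cases(self):
        assert zero_crossings(np.array([1.0, -1, 1, -1]), threshold=0.1) == 3
        assert zero_crossings(np.full(10, 0.7), threshold=0.01) == 0
        eps = 1e-4
        assert zero_crossings(np.array([eps, -eps, eps]), threshold=1.0) == 0

    def test_ssc_enumerated_cases(self):
        assert slope_sign_changes(np.array([0.0, 1, 0, 1, 0]), threshold=0.5) == 3
        assert slope_sign_changes(np.arange(10.0), threshold=0.0) == 0
        assert slope_sign_changes(np.array([0.0, 1, 0, 1, 0]),
                                  threshold=np.inf) == 0

    def test_wl_direct_case(self):
        assert waveform_length([0, 1, 0, 2]) == pytest.approx(4.0)
        assert waveform_length(np.full(8, 3.3)) == 0.0

    def test_wl_telescopes_on_monotone_series(self, rng):
        x = np.sort(rng.normal(size=40))
        assert waveform_length(x) == pytest.approx(x[-1] - x[0])

    def test_scaling_invariance_of_counts(self, rng):
        x = rng.normal(size=200)
        # the ZC threshold follows std(x), so positive scaling leaves the
        # count alone; the SSC comparison is against a *product* of
        # differences, so its threshold must scale quadratically
        assert zero_crossings(x) == zero_crossings(5.0 * x)
        thr = 0.05 * float(np.std(x))
        assert slope_sign_changes(x, thr) == \
            slope_sign_changes(5.0 * x, 25.0 * thr)


class TestOracleAgreement:
    def test_thousand_random_series(self, rng):
        """All scalar features match direct-summation oracles to 1e-12."""
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            x = rng.normal(scale=float(rng.uniform(0.1, 5.0)), size=n)
            thr = float(rng.uniform(0.0, 0.5))
            assert mav(x) == pytest.approx(mav_oracle(x), abs=1e-12)
            assert zero_crossings(x, thr) == zc_oracle(list(x), thr)
            assert slope_sign_changes(x, thr) == ssc_oracle(list(x), thr)
            assert waveform_length(x) == pytest.approx(wl_oracle(list(x)),
                                                       abs=1e-12)

    def test_axis_features_match_oracle(self, rng):
        for _ in range(200):
            stage = rng.normal(size=(3, int(rng.integers(5, 40))))
            np.testing.assert_allclose(axis_features(stage),
                                       axis_oracle(stage), atol=1e-12)

    def test_orientation_is_channel_mean(self, rng):
        stage = rng.normal(size=(3, 30))
        np.testing.assert_allclose(
            orientation_features(stage),
            [sum(ch) / len(ch) for ch in stage], atol=1e-12)


class TestAxisFeatures:
    def test_pure_single_axis_motion(self):
        t = np.linspace(0, 4 * np.pi, 200)
        stage = np.vstack([np.sin(t), np.zeros_like(t), np.zeros_like(t)])
        out = axis_features(stage)
        assert out[0] > 0
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_shared_normalisation_case(self):
        # two identical unit-norm zero-mean channels, third silent:
        # Snorm = 2 and r12 = |S1.S2| / Snorm = 1/2
        s1 = np.array([1.0, -1.0]) / np.sqrt(2)
        stage = np.vstack([s1, s1, np.zeros(2)])
        out = axis_features(stage)
        assert out[3] == pytest.approx(0.5)
        assert out[4] == out[5] == 0.0

    def test_negating_one_channel_flips_its_r_signs(self, rng):
        stage = rng.normal(size=(3, 40))
        base = axis_features(stage)
        flipped = axis_features(stage * np.array([[1.0], [-1.0], [1.0]]))
        np.testing.assert_allclose(flipped[[0, 1, 2]], base[[0, 1, 2]])
        assert flipped[3] == pytest.approx(-base[3])   # r12
        assert flipped[5] == pytest.approx(-base[5])   # r23
        assert flipped[4] == pytest.approx(base[4])    # r13 untouched

    def test_offset_invariance(self, rng):
        stage = rng.normal(size=(3, 40))
        shifted = stage + np.array([[3.0], [-2.0], [10.0]])
        np.testing.assert_allclose(axis_features(shifted), axis_features(stage),
                                   atol=1e-10)

    def test_all_zero_stage_is_guarded(self):
        np.testing.assert_array_equal(axis_features(np.zeros((3, 10))),
                                      np.zeros(6))

    def test_rotation_shares_the_contract(self, rng):
        stage = rng.normal(size=(3, 25))
        np.testing.assert_array_equal(rotation_features(stage),
                                      axis_features(stage))


class TestOrientationFeatures:
    def test_static_palm_down_pose(self):
        stage = np.tile([[0.0], [0.0], [1.0]], 50)
        np.testing.assert_allclose(orientation_features(stage), [0, 0, 1])

    def test_gravity_recovered_under_oscillation(self, rng):
        t = np.linspace(0, 6 * np.pi, 600)
        osc = np.vstack([np.sin(t), np.cos(2 * t), np.sin(3 * t)])
        stage = osc + np.array([[0.0], [0.6], [0.8]])
        np.testing.assert_allclose(orientation_features(stage), [0, 0.6, 0.8],
                                   atol=0.02)

    def test_stationary_input_is_length_invariant(self):
        stage = np.tile([[0.2], [0.3], [0.9]], 200)
        np.testing.assert_allclose(orientation_features(stage[:, :50]),
                                   orientation_features(stage))


class TestArCoefficients:
    def test_recovers_known_ar4_process(self, rng):
        a = np.array([-0.5, 0.3, -0.2, 0.1])   # x(n) = w(n) - sum a_k x(n-k)
        assert np.all(np.abs(np.roots(np.concatenate(([1.0], a)))) < 1)
        w = rng.normal(size=10_000)
        x = lfilter([1.0], np.concatenate(([1.0], a)), w)
        est = ar_coefficients(x, p=4)
        np.testing.assert_allclose(est, a, atol=0.1)

    def test_white_noise_coefficients_near_zero(self, rng):
        est = ar_coefficients(rng.normal(size=10_000), p=4)
        assert np.all(np.abs(est) < 0.1)

    def test_output_length_is_order(self, rng):
        assert ar_coefficients(rng.normal(size=100)).shape == (4,)

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            est = ar_coefficients(np.full(100, 1.0))
        np.testing.assert_array_equal(est, np.zeros(4))


class TestHandshapeFeatures:
    def test_frame_and_feature_counts(self, rng):
        stage = rng.normal(size=(4, 1000))
        feats = handshape_features(stage, WindowingSpec(128, 64))
        assert feats.shape == (14, 32)

    def test_channel_major_ordering(self, rng):
        stage = rng.normal(size=(4, 256))
        stage[2] *= 10.0
        feats = handshape_features(stage, WindowingSpec(256, 256))
        # MAV occupies slot 0 of each 8-feature channel block
        mavs = feats[0, [0, 8, 16, 24]]
        np.testing.assert_allclose(
            mavs, [mav(stage[c]) for c in range(4)], atol=1e-12)
        assert np.argmax(mavs) == 2

    def test_all_zero_semg(self, rng):
        with pytest.warns(UserWarning):
            feats = handshape_features(np.zeros((4, 300)), WindowingSpec(128, 64))
        np.testing.assert_array_equal(feats, 0.0)

    def test_deterministic_across_calls(self, rng):
        stage = rng.normal(size=(4, 500))
        a = handshape_features(stage)
        b = handshape_features(stage)
        np.testing.assert_array_equal(a, b)


class TestTrajectoryFeatures:
    def test_shape_is_always_64_by_6(self, rng):
        out = trajectory_features(rng.normal(size=(3, 230)),
                                  rng.normal(size=(3, 230)))
        assert out.shape == (64, 6)

    def test_length_64_input_passes_through(self, rng):
        acc, gyro = rng.normal(size=(3, 64)), rng.normal(size=(3, 64))
        out = trajectory_features(acc, gyro)
        np.testing.assert_allclose(out[:, :3], acc.T, atol=1e-12)
        np.testing.assert_allclose(out[:, 3:], gyro.T, atol=1e-12)

    def test_time_reversal_reverses_rows(self, rng):
        acc, gyro = rng.normal(size=(3, 150)), rng.normal(size=(3, 150))
        fwd = trajectory_features(acc, gyro)
        rev = trajectory_features(acc[:, ::-1], gyro[:, ::-1])
        np.testing.assert_allclose(rev, fwd[::-1], atol=1e-9)
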