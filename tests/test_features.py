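"""Window features: definitions, the 40-feature layout, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import preimpact as pi
from preimpact.errors import UsageError
from preimpact.features import FEATURE_NAMES, Window, absdiff, fft5, spectral_energy, zcr

from conftest import make_recording


def dft_oracle(x):
    """O(N^2) direct DFT, independent of numpy.fft."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n)
    return (x[None, :] * np.exp(-2j * np.pi * np.outer(k, k) / n)).sum(axis=1)


def feature_oracle(window: Window) -> np.ndarray:
    """Direct per-feature formulas; mirrors the documented 40-feature order."""
    acc_m = np.sqrt((window.samples[:, 0:3] ** 2).sum(axis=1))
    gyro_m = np.sqrt((window.samples[:, 3:6] ** 2).sum(axis=1))
    pitch = window.samples[:, 6]   # EulerX
    yaw = window.samples[:, 7]     # EulerY
    roll = window.samples[:, 8]    # EulerZ
    out = []
    for x in (acc_m, gyro_m):
        mu = sum(x) / len(x)
        dft = dft_oracle(x)
        out += [mu, sum((x - mu) ** 2) / len(x), np.sqrt(sum(x ** 2) / len(x)),
                sum(xi > mu for xi in x), sum(abs(x - mu)) / len(x),
                *np.abs(dft[:5]), sum(np.abs(dft) ** 2) / len(x)]
    for x in (pitch, roll, yaw):
        mu = sum(x) / len(x)
        dft = dft_oracle(x)
        out += [mu, np.sqrt(sum((x - mu) ** 2) / len(x)),
                np.sqrt(sum(x ** 2) / len(x)), sum(xi > mu for xi in x),
                sum(abs(x - mu)) / len(x), sum(np.abs(dft) ** 2) / len(x)]
    return np.array(out, dtype=float)


class TestSlidingWindows:
    @pytest.mark.parametrize("n,width,stride,expected", [
        (100, 50, 50, 2),
        (100, 50, 10, 6),
        (49, 50, 10, 0),    # recording shorter than one window
        (50, 50, 10, 1),
    ])
    def test_window_count(self, n, width, stride, expected):
        rec = make_recording(n=n)
        assert len(pi.sliding_windows(rec, width, stride)) == expected

    def test_offsets_and_end_frames(self):
        ws = pi.sliding_windows(make_recording(n=100), 50, 25)
        assert [w.start_frame for w in ws] == [1, 26, 51]
        assert ws[0].end_frame == 50


class TestScalarFeatures:
    @pytest.mark.parametrize("x,expected", [
        ([1, 2, 3], 1),          # only 3 exceeds the mean 2
        ([5, 5, 5, 5], 0),       # constant window
        ([0, 10, 0, 10], 2),
    ])
    def test_zcr(self, x, expected):
        assert zcr(np.array(x, float)) == expected

    @pytest.mark.parametrize("x,expected", [
        ([1, 2, 3], 2 / 3),
        ([7, 7, 7], 0.0),
        ([0, 10], 5.0),
    ])
    def test_absdiff(self, x, expected):
        assert absdiff(np.array(x, float)) == pytest.approx(expected)

    def test_fft5_constant_and_zero(self):
        np.testing.assert_allclose(fft5(np.ones(8)), [8, 0, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fft5(np.zeros(8)), 0.0)

    def test_fft5_pure_tone(self):
        # cos(2*pi*t/N) over N=50: bin 1 magnitude N/2, others ~0
        n = 50
        x = np.cos(2 * np.pi * np.arange(n) / n)
        mags = fft5(x)
        assert mags[1] == pytest.approx(n / 2)
        np.testing.assert_allclose(mags[[0, 2, 3, 4]], 0.0, atol=1e-9)

    def test_fft5_requires_five_samples(self):
        with pytest.raises(UsageError):
            fft5(np.ones(4))

    def test_spectral_energy_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        # sum |X_k|^2 / N equals sum x^2 by Parseval for the unnormalized DFT
        assert spectral_energy(x) == pytest.approx(np.sum(x ** 2))
        assert spectral_energy(np.array([1.0, 1, 1, 1])) == pytest.approx(4.0)


class TestExtractFeatures:
    def test_default_window_yields_exactly_40_features(self, fall_trial):
        rec, _ = fall_trial
        w = pi.sliding_windows(rec)[0]
        fv = pi.extract_features(w)
        assert len(fv.values) == 40
        assert fv.names == FEATURE_NAMES
        assert np.all(np.isfinite(fv.values))

    def test_constant_window_degenerates(self):
        samples = np.tile([0.0, -1.0, 0.0, 0, 0, 0, 15.0, 5.0, -10.0], (50, 1))
        fv = pi.extract_features(Window(samples=samples, start_frame=1))
        by_name = dict(zip(fv.names, fv.values))
        for sig, const in [("acc_m", 1.0), ("pitch", 15.0), ("roll", -10.0)]:
            assert by_name[f"{sig}_mean"] == pytest.approx(const)
            assert by_name[f"{sig}_rms"] == pytest.approx(abs(const))
            assert by_name[f"{sig}_zcr"] == 0
            assert by_name[f"{sig}_absdiff"] == pytest.approx(0, abs=1e-12)
        assert by_name["acc_m_var"] == pytest.approx(0, abs=1e-12)
        assert by_name["pitch_sd"] == pytest.approx(0, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            w = Window(samples=rng.normal(scale=3.0, size=(50, 9)), start_frame=1)
            got = pi.extract_features(w).values
            want = feature_oracle(w)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_translation_equivariance(self, fall_trial):
        rec, _ = fall_trial
        ws = pi.sliding_windows(rec, 50, 10)
        w_shifted = Window(samples=ws[3].samples, start_frame=999)
        np.testing.assert_array_equal(pi.extract_features(ws[3]).values,
                                      pi.extract_features(w_shifted).values)


class TestNormalizer:
    def test_two_point_training_set(self):
        X = np.array([[0.0], [2.0]])
        norm = pi.fit_normalizer(X)
        np.testing.assert_allclose(norm.transform(X), [[-1.0], [1.0]])

    def test_training_set_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(loc=5, scale=3, size=(200, 4))
        Z = pi.fit_normalizer(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-9)

    def test_constant_feature_centered_not_scaled(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        Z = pi.fit_normalizer(X).transform(X)
        np.testing.assert_allclose(Z[:, 0], 0.0, atol=1e-12)

    def test_apply_before_fit_is_usage_error(self):
        with pytest.raises(UsageError):
            pi.Normalizer().transform(np.ones((3, 2)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=60))
def test_zcr_absdiff_invariants(values):
    """ZCR is bounded by N-1; ABSDIFF is non-negative and shift-invariant."""
    x = np.array(values)
    assert 0 <= zcr(x) <= len(x) - 1
    assert absdiff(x) >= 0
    assert absdiff(x + 42.0) == pytest.approx(absdiff(x), abs=1e-9)
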