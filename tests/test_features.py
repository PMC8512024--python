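"""Feature-bank correctness: closed forms, brute-force loop oracles,
scale equivariance, registry composition."""

import math

import numpy as np
import pytest

import sitsense as s
from sitsense.features import EPS, NonFiniteFeatureError, default_registry
from sitsense.preprocess import ALL_CHANNELS

# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain Python loops, no numpy reductions)
# ---------------------------------------------------------------------------

def oracle_mav(xs):
    return sum(abs(v) for v in xs) / len(xs)


def oracle_var(xs):
    mu = sum(xs) / len(xs)
    return sum((v - mu) ** 2 for v in xs) / len(xs)


def oracle_sd(xs):
    return math.sqrt(oracle_var(xs))


def oracle_skew(xs):
    mu = sum(xs) / len(xs)
    sd = oracle_sd(xs)
    if sd == 0:
        return 0.0
    return sum(((v - mu) / sd) ** 3 for v in xs) / len(xs)


def oracle_rms(xs):
    return math.sqrt(sum(v * v for v in xs) / len(xs))


def oracle_ssi(xs):
    return sum(v * v for v in xs)


def oracle_we(xs):
    tot = sum(v * v for v in xs)
    if tot == 0:
        return 0.0
    acc = 0.0
    for v in xs:
        p = v * v / tot
        if p > 0:
            acc -= p * math.log(p)
    return acc


def oracle_lee(xs):
    return sum(math.log2(v * v + EPS) for v in xs)


def oracle_hm(xs):
    return len(xs) / sum(1.0 / (abs(v) + EPS) for v in xs)


ORACLES = {
    s.mav: oracle_mav,
    s.variance: oracle_var,
    s.std_dev: oracle_sd,
    s.skewness: oracle_skew,
    s.rms: oracle_rms,
    s.ssi: oracle_ssi,
    s.wavelet_entropy: oracle_we,
    s.log_energy_entropy: oracle_lee,
    s.harmonic_mean: oracle_hm,
}


class TestClosedForms:
    def test_magnitude(self):
        assert s.magnitude(3, 4, 0) == 5
        assert s.magnitude(0, 0, 0) == 0
        assert s.magnitude(1, 1, 1) == pytest.approx(math.sqrt(3))

    def test_mav(self):
        assert s.mav([1, -2, 3]) == 2
        assert s.mav([0, 0, 0]) == 0

    def test_var_sd(self):
        assert s.variance([1, 2, 3]) == pytest.approx(2 / 3)
        assert s.std_dev([1, 2, 3]) == pytest.approx(math.sqrt(2 / 3))
        assert s.variance([5, 5, 5]) == 0 == s.std_dev([5, 5, 5])

    def test_skewness_symmetry_and_antisymmetry(self):
        assert s.skewness([-1, 0, 1]) == 0
        x = [0.3, -1.2, 2.0, 0.1, 4.0]
        assert s.skewness([-v for v in x]) == pytest.approx(-s.skewness(x))

    def test_skewness_as_printed_variant(self):
        x = [0.0, 0.0, 0.0, 1.0]
        mu, sd = 0.25, math.sqrt(3) / 4
        m3 = sum((v - mu) ** 3 for v in x) / 4
        assert s.skewness(x, as_printed=True) == pytest.approx(m3 / sd)
        assert s.skewness(x) == pytest.approx(m3 / sd**3)

    def test_rms_ssi(self):
        assert s.rms([3, 4]) == pytest.approx(math.sqrt(12.5))
        assert s.ssi([3, 4]) == 25
        assert s.rms([0, 0]) == 0 == s.ssi([0, 0])

    def test_ssi_equals_n_rms_squared(self, rng):
        x = rng.normal(size=64)
        assert s.ssi(x) == pytest.approx(len(x) * s.rms(x) ** 2)

    def test_wavelet_entropy_limits(self):
        x = np.full(50, 0.4)
        assert s.wavelet_entropy(x) == pytest.approx(math.log(50))
        single = np.zeros(50)
        single[7] = 2.0
        assert s.wavelet_entropy(single) == 0
        assert s.wavelet_entropy(np.zeros(50)) == 0

    def test_lee_closed_forms(self):
        assert s.log_energy_entropy(np.ones(5)) == pytest.approx(0, abs=1e-9)
        assert s.log_energy_entropy([2, 2]) == pytest.approx(4, abs=1e-9)

    def test_harmonic_mean_closed_forms(self):
        assert s.harmonic_mean([1, 2, 4]) == pytest.approx(12 / 7)
        assert s.harmonic_mean([-3, 3, 3]) == pytest.approx(3)

    def test_empty_window_rejected(self):
        for fn in (s.mav, s.variance, s.rms, s.ssi):
            with pytest.raises(ValueError):
                fn([])


class TestBruteForceOracles:
    """Every statistic agrees with an independent loop oracle on random
    windows to 1e-10 relative tolerance."""

    N_WINDOWS = 1000

    @pytest.mark.parametrize("fn", list(ORACLES), ids=lambda f: f.__name__)
    def test_against_loop_oracle(self, fn, rng):
        X = rng.normal(0, 1.5, size=(self.N_WINDOWS, 50))
        fast = fn(X)
        for i in range(self.N_WINDOWS):
            expected = ORACLES[fn](list(X[i]))
            assert fast[i] == pytest.approx(expected, rel=1e-10, abs=1e-10)


class TestScaleEquivariance:
    def test_linear_quadratic_invariant(self, rng):
        x = rng.normal(size=(20, 50))
        c = 3.7
        np.testing.assert_allclose(s.mav(c * x), c * s.mav(x))
        np.testing.assert_allclose(s.std_dev(c * x), c * s.std_dev(x))
        np.testing.assert_allclose(s.rms(c * x), c * s.rms(x))
        np.testing.assert_allclose(s.variance(c * x), c**2 * s.variance(x))
        np.testing.assert_allclose(s.ssi(c * x), c**2 * s.ssi(x))
        np.testing.assert_allclose(s.skewness(c * x), s.skewness(x), atol=1e-12)
        np.testing.assert_allclose(s.wavelet_entropy(c * x), s.wavelet_entropy(x))


class TestRegistry:
    def test_default_registry_size_84(self):
        reg = default_registry()
        assert len(reg) == 84
        assert len(set(reg)) == 84

    def test_published_style_names_present(self):
        reg = default_registry()
        for name in ("Y-accelerometer-MAV", "X-gyroscope-WE", "Total-acceleration"):
            assert name in reg

    def test_extraction_shape_and_finiteness(self, small_fm):
        assert small_fm.values.shape[1] == 84
        assert np.all(np.isfinite(small_fm.values))
        assert set(small_fm.labels) <= set(s.ACTIVITIES)

    def test_constant_window_closed_forms(self):
        win = s.Window(
            channels={ch: np.full(50, 0.5) for ch in ALL_CHANNELS},
            label="A5",
            subject_id=0,
            start_index=0,
        )
        fm = s.extract_features([win])
        get = dict(zip(fm.feature_names, fm.values[0]))
        assert get["X-accelerometer-MAV"] == pytest.approx(0.5)
        assert get["X-accelerometer-Var"] == 0
        assert get["X-accelerometer-skewness"] == 0
        assert get["X-accelerometer-WE"] == pytest.approx(math.log(50))
        assert get["Total-acceleration"] == pytest.approx(0.5)

    def test_nonfinite_feature_aborts_with_name(self):
        chans = {ch: np.full(50, 0.5) for ch in ALL_CHANNELS}
        chans["Y-gyroscope"] = np.full(50, np.inf)
        win = s.Window(channels=chans, label="A5", subject_id=0, start_index=0)
        with pytest.raises(NonFiniteFeatureError, match="Y-gyroscope"):
            s.extract_features([win])

    def test_matrix_bit_stable_across_runs(self, small_config):
        def build():
            rec = s.generate_recording(small_config, subject_id=1)
            return s.extract_features(s.make_windows(rec, s.WindowSpec()))

        a, b = build(), build()
        assert np.array_equal(a.values, b.values)
        assert list(a.labels) == list(b.labels)

    def test_csv_round_trip(self, small_fm, tmp_path):
        path = tmp_path / "fm.csv"
        small_fm.to_csv(path)
        back = s.FeatureMatrix.from_csv(path)
        assert back.feature_names == small_fm.feature_names
        np.testing.assert_allclose(back.values, small_fm.values, rtol=1e-10)
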