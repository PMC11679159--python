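import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lagfoci as lf
from lagfoci.exceptions import (
    ChannelLookupError,
    InsufficientOverlapError,
    UndefinedCorrelationError,
)
from .conftest import naive_lagged_r


class TestLaggedCorrelation:
    def test_exact_shifted_copy_gives_plus_one(self, rng):
        p = rng.standard_normal(500)
        q = np.concatenate([np.zeros(3), p])  # q repeats p after 3 samples
        assert lf.lagged_correlation(p, q, 30.0, 100.0) == pytest.approx(1.0)

    def test_negated_copy_gives_minus_one(self, rng):
        p = rng.standard_normal(500)
        q = np.concatenate([np.zeros(3), -p])
        assert lf.lagged_correlation(p, q, 30.0, 100.0) == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # pairs (1,1) (2,2) (3,3) (4,5): cov 1.625, sds 1.1180 and 1.4790
        p = [1.0, 2.0, 3.0, 4.0]
        q = [9.0, 1.0, 2.0, 3.0, 5.0]  # q_{i+1} = (1, 2, 3, 5)
        r = lf.lagged_correlation(p, q, 10.0, 100.0)
        assert r == pytest.approx(1.625 / (1.1180339887 * 1.479019946), abs=1e-9)
        assert r == pytest.approx(0.9827, abs=1e-4)

    def test_constant_segment_raises_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            lf.lagged_correlation(np.ones(10), np.arange(10.0), 0.0, 100.0)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            lf.lagged_correlation(np.arange(4.0), np.arange(4.0), 20.0, 100.0)

    def test_fractional_sample_lag_rejected(self):
        with pytest.raises(ValueError, match="whole sample"):
            lf.lagged_correlation(np.arange(10.0), np.arange(10.0), 15.0, 100.0)

    def test_time_reversal_symmetry(self, rng):
        # r_pq(+d) equals the coefficient of the swapped pair on the same
        # aligned pairs (a negative lag expressed by swapping the order)
        p = rng.standard_normal(200)
        q = rng.standard_normal(200)
        shift = 5
        forward = lf.lagged_correlation(p, q, 50.0, 100.0)
        swapped = lf.lagged_correlation(q[shift:], p, 0.0, 100.0)
        assert forward == pytest.approx(swapped, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        p = rng.standard_normal(300)
        q = rng.standard_normal(300)
        base = lf.lagged_correlation(p, q, 20.0, 100.0)
        assert lf.lagged_correlation(p, 3.5 * q + 7.0, 20.0, 100.0) == pytest.approx(base, abs=1e-12)
        assert lf.lagged_correlation(p, -2.0 * q + 1.0, 20.0, 100.0) == pytest.approx(-base, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        data=st.data(),
        n=st.integers(min_value=8, max_value=200),
        shift=st.integers(min_value=0, max_value=20),
    )
    def test_matches_naive_double_loop(self, data, n, shift):
        """The vectorised engine agrees with a literal two-pass evaluation."""
        seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
        gen = np.random.default_rng(seed)
        p = gen.normal(scale=10.0, size=n)
        q = gen.normal(scale=10.0, size=n + shift)
        fast = lf.lagged_correlation(p, q, shift * 10.0, 100.0)
        assert fast == pytest.approx(naive_lagged_r(p, q, shift), abs=1e-9)

    def test_null_sd_matches_one_over_sqrt_n(self):
        """For independent noise the sampling sd of r is about 1/sqrt(n)."""
        n, reps = 400, 1000
        gen = np.random.default_rng(99)
        rs = np.empty(reps)
        for i in range(reps):
            p = gen.standard_normal(n + 1)
            q = gen.standard_normal(n + 1)
            rs[i] = lf.lagged_correlation(p, q, 10.0, 100.0)
        assert abs(rs.std() - 1.0 / np.sqrt(n)) < 0.15 / np.sqrt(n)


class TestCorrelationCurve:
    def test_imposed_delay_is_argmax(self, delayed_pair_rec):
        curve = lf.correlation_curve(delayed_pair_rec, "A", "B")
        assert curve.lags_ms[np.argmax(curve.r)] == 30.0
        assert np.all(np.abs(curve.r) <= 1.0) and np.all(curve.n >= 3)

    def test_independent_noise_stays_near_zero(self, rng):
        rec = lf.Recording(["A", "B"], rng.standard_normal((2, 10_000)), 100.0)
        curve = lf.correlation_curve(rec, "A", "B")
        assert np.all(np.abs(curve.r) < 0.1)  # 99% bound at n = 1e4 is ~0.026

    def test_autocorrelation_of_ar1(self):
        gen = np.random.default_rng(5)
        phi = 0.9
        x = np.empty(20_000)
        x[0] = gen.standard_normal()
        eps = gen.standard_normal(len(x))
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + eps[i]
        rec = lf.Recording(["A", "B"], np.vstack([x, x]), 100.0)
        curve = lf.correlation_curve(rec, "A", "A", lf.LagGrid((10.0, 20.0, 30.0, 50.0)))
        shifts = (curve.lags_ms / 10).astype(int)
        np.testing.assert_allclose(curve.r, phi**shifts, atol=0.05)
        assert np.all(np.diff(curve.r) <= 0)

    def test_unknown_label(self, two_channel_rec):
        with pytest.raises(ChannelLookupError, match="Cz"):
            lf.correlation_curve(two_channel_rec, "A", "Cz")


class TestWindowedCorrelation:
    def test_single_window_reduces_to_direct_coefficient(self, rng):
        grid = lf.LagGrid((10.0, 50.0))
        wn, max_shift = 50, 5
        data = rng.standard_normal((2, wn + max_shift))
        rec = lf.Recording(["A", "B"], data, 100.0)
        wlc = lf.windowed_correlation(rec, "A", "B", grid, window_ms=500.0, step_ms=10.0)
        assert wlc.r.shape == (1, 2)
        for k, shift in enumerate((1, 5)):
            expected = np.corrcoef(data[0, :wn], data[1, shift : shift + wn])[0, 1]
            assert wlc.r[0, k] == pytest.approx(expected, abs=1e-12)

    def test_stationary_pair_windows_match_full_record(self, delayed_pair_rec):
        wlc = lf.windowed_correlation(
            delayed_pair_rec, "A", "B", window_ms=2000.0, step_ms=500.0
        )
        full = lf.correlation_curve(delayed_pair_rec, "A", "B")
        peak_col = int(np.argmax(full.r))
        # every window reproduces the dominant lag of the stationary structure
        assert np.all(np.argmax(wlc.r, axis=1) == peak_col)

    def test_constant_window_is_missing_not_zero(self):
        x = np.sin(np.arange(300) / 5.0)
        y = x.copy()
        y[:80] = 4.2  # first windows see a constant aligned segment
        rec = lf.Recording(["A", "B"], np.vstack([y, x]), 100.0)
        wlc = lf.windowed_correlation(rec, "A", "B", lf.LagGrid((10.0,)), 500.0, 10.0)
        assert np.isnan(wlc.r[0, 0])
        assert np.isfinite(wlc.r[-1, 0])

    def test_too_short_record_rejected(self, rng):
        rec = lf.Recording(["A", "B"], rng.standard_normal((2, 50)), 100.0)
        with pytest.raises(ValueError, match="too short"):
            lf.windowed_correlation(rec, "A", "B")

    def test_window_times_strictly_increasing(self, delayed_pair_rec):
        wlc = lf.windowed_correlation(delayed_pair_rec, "A", "B")
        assert np.all(np.diff(wlc.times) > 0)
        assert np.all(np.abs(wlc.r[np.isfinite(wlc.r)]) <= 1.0)


class TestLatencyAtThreshold:
    @pytest.mark.parametrize(
        "r_by_lag, expected",
        [
            ({10: 0.8, 20: 0.75, 30: 0.71, 50: 0.65, 70: 0.2}, 30.0),
            ({10: 0.5, 20: 0.3, 30: 0.1, 50: 0.0, 70: -0.2}, 0.0),
            # high everywhere except the final grid lag: report 400, not 500
            ({10: 0.89, 20: 0.8, 30: 0.8, 50: 0.75, 70: 0.72, 100: 0.71,
              200: 0.7, 250: 0.7, 300: 0.71, 400: 0.7, 500: 0.6}, 400.0),
        ],
    )
    def test_largest_qualifying_lag(self, r_by_lag, expected):
        lags = sorted(r_by_lag)
        curve = lf.LagCurve(
            ("p", "q"),
            np.array(lags, dtype=float),
            np.array([r_by_lag[l] for l in lags]),
            np.full(len(lags), 100),
        )
        assert lf.latency_at_threshold(curve) == expected
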