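"""Time-domain and nonlinear HRV features against hand computations and
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afpredict import (
    approximate_entropy,
    ar_residual_power,
    multiscale_entropy,
    poincare,
    sample_entropy,
    time_domain,
)

from .conftest import make_constant_rr, make_rr


# --------------------------------------------------------------------------
# independent brute-force entropy oracles (plain double loops)
# --------------------------------------------------------------------------

def sampen_bruteforce(x, m, r):
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def apen_bruteforce(x, m, r):
    def phi(mm):
        n = len(x)
        nm = n - mm + 1
        total = 0.0
        for i in range(nm):
            c = 0
            for j in range(nm):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += np.log(c / nm)
        return total / nm

    return phi(m) - phi(m + 1)


# --------------------------------------------------------------------------
# time domain
# --------------------------------------------------------------------------

class TestTimeDomain:
    def test_nn50_pnn50_hand_count(self):
        rr = make_rr([800, 860, 800, 820] * 3)  # pad to meet 10-interval floor
        td = time_domain(rr)
        # per period of 4: diffs 60, -60, 20, -20 -> 2 exceed 50 ms
        assert td.nn50 == 6
        assert td.pnn50 == pytest.approx(6 / 12)

    def test_sdnn_rmssd_formula(self):
        rr = make_rr([800, 860, 800, 820, 800, 860, 800, 820, 800, 860])
        x = rr.intervals
        td = time_domain(rr)
        assert td.sdnn == pytest.approx(np.std(x, ddof=1), rel=1e-12)
        rmssd = np.sqrt(np.mean(np.diff(x) ** 2))
        assert td.rmssd == pytest.approx(rmssd, rel=1e-12)
        assert td.rmssd_norm == pytest.approx(rmssd / x.mean(), rel=1e-12)

    def test_constant_series_degenerate_conventions(self):
        td = time_domain(make_constant_rr(100))
        assert td.sdnn == 0
        assert td.nn50 == 0
        assert td.rmssd_norm == 0
        assert td.skewness == 0
        assert td.tri_index == pytest.approx(1.0)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            time_domain(make_rr([800] * 5))

    def test_nn20_variant_threshold(self):
        rr = make_rr([800, 830, 800, 830, 800, 830, 800, 830, 800, 830])
        assert time_domain(rr).nn50 == 0
        assert time_domain(rr, nn_threshold_ms=20.0).nn50 == 9


# --------------------------------------------------------------------------
# Poincaré
# --------------------------------------------------------------------------

class TestPoincare:
    def test_constant_series_degenerate(self):
        sd1, sd2, ratio = poincare(make_constant_rr(50))
        assert (sd1, sd2, ratio) == (0.0, 0.0, 0.0)

    def test_alternating_series_closed_form(self):
        # 800/810 alternation: population Var(RR)=25, Var(dRR)=100
        rr = make_rr([800, 810] * 200)
        sd1, sd2, _ = poincare(rr)
        assert sd1 == pytest.approx(np.sqrt(50.0), rel=5e-3)  # 7.071 ms
        assert sd2 == pytest.approx(0.0, abs=0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(300, 2000), min_size=5, max_size=80))
    def test_sd_identity(self, vals):
        """SD1² + SD2² = 2·Var(RR) whenever SD2 does not truncate at 0."""
        x = np.asarray(vals)
        rr = make_rr(x)
        sd1, sd2, _ = poincare(rr)
        if 2 * np.var(x, ddof=1) >= 0.5 * np.var(np.diff(x), ddof=1):
            assert sd1**2 + sd2**2 == pytest.approx(
                2 * np.var(x, ddof=1), rel=1e-9, abs=1e-9
            )


# --------------------------------------------------------------------------
# entropies
# --------------------------------------------------------------------------

class TestEntropies:
    def test_constant_series_zero(self):
        rr = make_constant_rr(80)
        assert sample_entropy(rr) == 0.0
        assert approximate_entropy(rr) == 0.0

    @pytest.mark.parametrize("n", [60, 100, 120])
    def test_sampen_matches_bruteforce(self, n):
        rng = np.random.default_rng(n)
        x = rng.uniform(700, 900, n)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(make_rr(x), m=2, r_tol=r) == pytest.approx(
            sampen_bruteforce(x, 2, r), abs=1e-12
        )

    @pytest.mark.parametrize("n", [60, 100, 120])
    def test_apen_matches_bruteforce(self, n):
        rng = np.random.default_rng(1000 + n)
        x = rng.uniform(700, 900, n)
        r = 0.2 * np.std(x, ddof=1)
        assert approximate_entropy(make_rr(x), m=2, r_tol=r) == pytest.approx(
            apen_bruteforce(x, 2, r), abs=1e-12
        )

    def test_alternating_series_perfectly_regular(self):
        rr = make_rr([800, 810] * 50)
        assert sample_entropy(rr, m=2, r_tol=2.0) == 0.0

    def test_apen_translation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(700, 900, 90)
        a = approximate_entropy(make_rr(x), r_tol=20.0)
        b = approximate_entropy(make_rr(x + 150.0), r_tol=20.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_mse_scale1_equals_sampen(self, nsr_rr):
        mse = multiscale_entropy(nsr_rr)
        assert mse[0] == sample_entropy(nsr_rr)

    def test_mse_constant_all_zero(self):
        mse = multiscale_entropy(make_constant_rr(300))
        assert np.all(mse == 0.0)

    def test_mse_short_scales_undefined(self):
        mse = multiscale_entropy(make_constant_rr(120), scales=5)
        # scales needing >= 50 coarse points: 1 and 2 only
        assert np.all(mse[:2] == 0.0)
        assert np.all(np.isnan(mse[2:]))

    def test_white_noise_mse_nonincreasing_on_average(self):
        vals = np.zeros((20, 3))
        for s in range(20):
            x = np.random.default_rng(s).normal(800, 30, 400)
            vals[s] = multiscale_entropy(make_rr(x), scales=3)
        med = np.median(vals, axis=0)
        assert np.all(np.diff(med) <= 1e-9)


# --------------------------------------------------------------------------
# AR residual power
# --------------------------------------------------------------------------

class TestArResidual:
    def test_constant_series_zero(self):
        assert ar_residual_power(make_constant_rr(200)) == 0.0

    def test_white_noise_recovers_variance(self):
        est = [
            ar_residual_power(
                make_rr(np.random.default_rng(s).normal(800, 30, 300))
            )
            for s in range(20)
        ]
        assert np.median(est) == pytest.approx(900.0, rel=0.15)

    def test_ar1_innovation_variance(self):
        est = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            e = rng.normal(0, 1.0, 600)
            x = np.empty(500)
            prev = 0.0
            for i, ei in enumerate(e[100:]):
                prev = 0.5 * prev + ei
                x[i] = prev
            est.append(ar_residual_power(make_rr(x + 800.0)))
        assert np.median(est) == pytest.approx(1.0, rel=0.15)

    def test_yule_walker_close_to_lstsq(self, nsr_rr):
        a = ar_residual_power(nsr_rr, method="lstsq")
        b = ar_residual_power(nsr_rr, method="yule-walker")
        assert a == pytest.approx(b, rel=0.2)

    def test_pac_rate_increases_residual_power(self):
        """Frequent ectopy raises the unpredictable power (the feature's premise)."""
        from afpredict import SynthConfig, generate_nsr_rr

        med = []
        for rate in (0, 2, 6, 12):
            vals = [
                ar_residual_power(
                    generate_nsr_rr(
                        SynthConfig(seed=700 + s, pac_rate_per_min=rate)
                    ).rr
                )
                for s in range(20)
            ]
            med.append(np.median(vals))
        assert np.all(np.diff(med) > 0)


def test_features_time_origin_invariant(nsr_rr):
    """Shifting all beat times leaves every RR-based feature unchanged."""
    from afpredict import RRSeries

    shifted = RRSeries(
        nsr_rr.beat_times + 1000.0, nsr_rr.intervals, nsr_rr.flags
    )
    assert time_domain(shifted).sdnn == time_domain(nsr_rr).sdnn
    assert poincare(shifted) == poincare(nsr_rr)
    assert sample_entropy(shifted) == sample_entropy(nsr_rr)
    assert ar_residual_power(shifted) == ar_residual_power(nsr_rr)
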