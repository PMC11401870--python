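"""Hypoexponential loss-time model: closed forms, quadrature, simulation."""

import numpy as np
import pytest
from scipy import integrate

from dnarad.loss import (
    PoolDesign,
    expected_pool_loss_time,
    expected_strand_loss_time,
    hypoexponential_cdf,
    pool_loss_cdf,
    sensitivity_sweep,
    simulate_pool,
    strand_loss_cdf,
)

K = 2.0e-3  # per-copy hazard used throughout, s^-1


class TestStrandLossCdf:
    def test_zero_at_time_zero_and_one_at_infinity(self):
        d = PoolDesign(N=1, C=100, C_LLOD=10)
        assert strand_loss_cdf(d, K, 0.0) == 0.0
        assert strand_loss_cdf(d, K, 1e9) == pytest.approx(1.0)

    def test_two_copy_closed_form(self):
        # C=2, C_LLOD=1: both copies must fail; CDF = (1 - e^{-kt})^2
        d = PoolDesign(N=1, C=2, C_LLOD=1)
        t = np.linspace(0, 5 / K, 50)
        expected = (1 - np.exp(-K * t)) ** 2
        assert np.allclose(strand_loss_cdf(d, K, t), expected, atol=1e-12)
        # and the explicit hypoexponential with rates {2k, k} agrees
        assert np.allclose(
            hypoexponential_cdf([2 * K, K], t), expected, atol=1e-12
        )

    @pytest.mark.parametrize("C,llod", [(5, 1), (12, 3), (30, 10), (25, 24)])
    def test_binomial_tail_equals_hypoexponential(self, C, llod):
        d = PoolDesign(N=1, C=C, C_LLOD=llod)
        rates = d.stage_counts * K
        t = np.logspace(-1, 1.5, 40) / (K * C)
        a = strand_loss_cdf(d, K, t)
        b = hypoexponential_cdf(rates, t)
        assert np.max(np.abs(a - b)) < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            strand_loss_cdf(PoolDesign(N=1, C=2, C_LLOD=1), K, -1.0)


class TestExpectedStrandLossTime:
    def test_two_copy_stage_sum(self):
        d = PoolDesign(N=1, C=2, C_LLOD=1)
        assert expected_strand_loss_time(d, K) == pytest.approx(1.5 / K)

    def test_two_stage_case(self):
        llod = 7
        d = PoolDesign(N=1, C=llod + 1, C_LLOD=llod)
        expected = 1 / ((llod + 1) * K) + 1 / (llod * K)
        assert expected_strand_loss_time(d, K) == pytest.approx(expected)

    def test_matches_harmonic_sum(self):
        d = PoolDesign(N=1, C=1000, C_LLOD=10)
        harmonic = sum(1.0 / c for c in range(10, 1001)) / K
        assert expected_strand_loss_time(d, K) == pytest.approx(harmonic, rel=1e-12)

    def test_matches_survival_integral(self):
        d = PoolDesign(N=1, C=200, C_LLOD=10)
        m = expected_strand_loss_time(d, K)
        num, _ = integrate.quad(
            lambda u: 1.0 - strand_loss_cdf(d, K, m * u), 0, np.inf, limit=400
        )
        assert num * m == pytest.approx(m, rel=1e-6)


class TestPool:
    def test_single_strand_pool_reduces_to_strand(self):
        d1 = PoolDesign(N=1, C=50, C_LLOD=10)
        t = np.logspace(1, 4, 30)
        assert np.allclose(
            pool_loss_cdf(d1, K, t), strand_loss_cdf(d1, K, t), atol=1e-12
        )
        assert expected_pool_loss_time(d1, K) == pytest.approx(
            expected_strand_loss_time(d1, K), rel=1e-6
        )

    def test_pool_cdf_is_valid(self):
        d = PoolDesign(N=100, C=50, C_LLOD=10)
        t = np.logspace(0, 5, 80)
        F = pool_loss_cdf(d, K, t)
        assert np.all(np.diff(F) >= -1e-12)
        assert pool_loss_cdf(d, K, 0.0) == 0.0
        assert F[-1] == pytest.approx(1.0)

    def test_expected_time_non_increasing_in_n(self):
        vals = [
            expected_pool_loss_time(PoolDesign(N=n, C=100, C_LLOD=10), K)
            for n in (1, 10, 100, 1000, 10000)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_large_copy_numbers_stay_finite(self):
        # the naive hypoexponential product overflows here; the
        # binomial-tail formulation must not
        d = PoolDesign(N=7373, C=10**6, C_LLOD=10)
        et = expected_pool_loss_time(d, K)
        assert np.isfinite(et) and et > 0


class TestSimulatePool:
    def test_deterministic_given_seed(self):
        d = PoolDesign(N=3, C=20, C_LLOD=5)
        a = simulate_pool(d, K, n_reps=5, rng_seed=9)
        b = simulate_pool(d, K, n_reps=5, rng_seed=9)
        assert np.array_equal(a, b)
        assert len(simulate_pool(d, K, n_reps=1, rng_seed=1)) == 1

    def test_empirical_cdf_within_dkw_band(self):
        d = PoolDesign(N=10, C=50, C_LLOD=10)
        n = 2000
        times = np.sort(simulate_pool(d, K, n_reps=n, rng_seed=123))
        ecdf = np.arange(1, n + 1) / n
        analytic = pool_loss_cdf(d, K, times)
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))  # 99% DKW band
        assert np.max(np.abs(ecdf - analytic)) < eps

    def test_empirical_mean_matches_analytic(self):
        d = PoolDesign(N=10, C=50, C_LLOD=10)
        times = simulate_pool(d, K, n_reps=2000, rng_seed=77)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected_pool_loss_time(d, K)) < 3 * se


@pytest.fixture(scope="module")
def sweep_inputs():
    from dnarad.flux import jedec_reference
    from dnarad.xsec_model import REFERENCE_H2O, REFERENCE_NUC

    baseline = PoolDesign(N=50, C=100, L=150, theta=4.0, C_LLOD=10)
    return baseline, jedec_reference(), REFERENCE_NUC, REFERENCE_H2O


class TestSensitivitySweep:

    def test_copy_number_sweep_increases(self, sweep_inputs):
        baseline, flux, nuc, h2o = sweep_inputs
        df = sensitivity_sweep(baseline, "C", [50, 100, 500, 1000], flux, nuc, h2o)
        e = df["expected_loss_time_s"].to_numpy()
        assert np.all(np.diff(e) > 0)

    def test_length_sweep_decreases(self, sweep_inputs):
        baseline, flux, nuc, h2o = sweep_inputs
        df = sensitivity_sweep(baseline, "L", [50, 100, 200, 400], flux, nuc, h2o)
        e = df["expected_loss_time_s"].to_numpy()
        assert np.all(np.diff(e) < 0)

    def test_theta_sweep_decreases_and_flattens_without_water_channel(
        self, sweep_inputs
    ):
        from dnarad.xsec_model import PiecewiseCubicXSecModel

        baseline, flux, nuc, h2o = sweep_inputs
        df = sensitivity_sweep(baseline, "theta", [0.0, 4.0, 20.0], flux, nuc, h2o)
        e = df["expected_loss_time_s"].to_numpy()
        assert np.all(np.diff(e) < 0)
        zero = PiecewiseCubicXSecModel(beta=(-1000.0, 0, 0, 0))
        df0 = sensitivity_sweep(baseline, "theta", [0.0, 4.0, 20.0], flux, nuc, zero)
        e0 = df0["expected_loss_time_s"].to_numpy()
        assert np.allclose(e0, e0[0], rtol=1e-9)

    def test_invalid_grid_point_reported_not_raised(self, sweep_inputs):
        baseline, flux, nuc, h2o = sweep_inputs
        df = sensitivity_sweep(baseline, "C", [5, 100], flux, nuc, h2o)
        assert df.loc[0, "error"] != ""
        assert np.isnan(df.loc[0, "expected_loss_time_s"])
        assert df.loc[1, "error"] == ""


def test_design_invariants():
    with pytest.raises(ValueError):
        PoolDesign(N=0, C=100)
    with pytest.raises(ValueError):
        PoolDesign(N=1, C=10, C_LLOD=10)
    with pytest.raises(ValueError):
        PoolDesign(N=1, C=100, theta=-1.0)
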