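"""Piecewise cubic sigma(E) model: prediction, Poisson fit, covariates."""

import numpy as np
import pytest

from dnarad.mc import BARN_PER_NM2, CrossSectionEstimate
from dnarad.xsec_model import (
    REFERENCE_H2O,
    REFERENCE_NUC,
    PiecewiseCubicXSecModel,
    covariate_test,
    fit_piecewise,
    predict_sigma,
)


class TestPredict:
    def test_reference_nucleotide_model_at_1e8_ev(self):
        # direct evaluation of the published cubic at x = 8:
        # exp(-201.8137711 + 72.93892997*8 - 8.51321887*64 + 0.32227953*512)
        b = REFERENCE_NUC.beta
        expected = np.exp(b[0] + b[1] * 8 + b[2] * 64 + b[3] * 512)
        assert predict_sigma(REFERENCE_NUC, 1e8) == pytest.approx(expected)
        assert expected == pytest.approx(6.4159, rel=1e-4)

    def test_zero_outside_window(self):
        assert predict_sigma(REFERENCE_NUC, 1e5) == 0.0
        assert predict_sigma(REFERENCE_H2O, 1e11) == 0.0

    def test_zero_coefficients_give_one_barn(self):
        m = PiecewiseCubicXSecModel(beta=(0.0, 0.0, 0.0, 0.0))
        assert m.predict(1e8) == 1.0

    def test_continuous_inside_window(self):
        e = np.logspace(6.001, 9.999, 500)
        s = REFERENCE_NUC.predict(e)
        assert np.all(np.isfinite(s)) and np.all(s > 0)
        assert np.max(np.abs(np.diff(np.log(s)))) < 0.1

    def test_scaled_model_is_pointwise_multiple(self):
        m = REFERENCE_NUC.scaled(2.5)
        e = np.logspace(6.5, 9.5, 20)
        assert np.allclose(m.predict(e), 2.5 * REFERENCE_NUC.predict(e))

    def test_serialization_roundtrip(self):
        d = REFERENCE_H2O.to_dict()
        m = PiecewiseCubicXSecModel.from_dict(d)
        assert m.beta == REFERENCE_H2O.beta
        assert m.window == REFERENCE_H2O.window


def synth_estimates(
    beta,
    rng,
    n_energies=40,
    n_reps=4,
    thicknesses=None,
    thickness_slope=0.0,
    n_impacts=10**8,
    n_mol=200,
):
    """Poisson hit counts from a known cubic log sigma(E) model.

    Expected count = sigma(E) * exp(thickness_slope * thickness)
    * n_impacts * n_mol / A_barn; one estimate per (energy, replicate).
    """
    x = np.linspace(6.0, 10.0, n_energies)
    area_barn = 1.0 * BARN_PER_NM2
    out = []
    if thicknesses is None:
        thicknesses = [100.0]
    for t in thicknesses:
        for xi in x:
            log_sigma = beta[0] + beta[1] * xi + beta[2] * xi**2 + beta[3] * xi**3
            mean = (
                np.exp(log_sigma + thickness_slope * t)
                * n_impacts * n_mol / area_barn
            )
            for _ in range(n_reps):
                hits = int(rng.poisson(mean))
                out.append(
                    CrossSectionEstimate(
                        energy=10.0**xi,
                        thickness=t,
                        gc_fraction=0.5,
                        hits_nucleotide=hits,
                        hits_water=0,
                        n_impacts=n_impacts,
                        sigma_nuc_hat=hits * area_barn / (n_impacts * n_mol),
                        sigma_h2o_hat=0.0,
                        n_nucleotides_in_area=n_mol,
                        n_waters_in_area=0,
                        sample_area=1.0,
                    )
                )
    return out


class TestFitPiecewise:
    def test_parameter_recovery_on_poisson_data(self):
        rng = np.random.default_rng(0)
        est = synth_estimates(REFERENCE_NUC.beta, rng)
        model = fit_piecewise(est, response="nucleotide")
        for b_hat, b_true, se in zip(model.beta, REFERENCE_NUC.beta, model.beta_se):
            assert abs(b_hat - b_true) < 3 * se

    def test_fitted_model_reproduces_training_means(self):
        rng = np.random.default_rng(1)
        est = synth_estimates(REFERENCE_NUC.beta, rng, n_reps=8)
        model = fit_piecewise(est, response="nucleotide")
        e = np.logspace(6.2, 9.8, 15)
        assert np.allclose(
            model.predict(e), REFERENCE_NUC.predict(e), rtol=0.5
        )

    def test_null_quadratic_and_cubic_terms_not_significant(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        est = synth_estimates((np.log(2.0), 0.0, 0.0, 0.0), rng, n_mol=2000)
        model = fit_piecewise(est, response="nucleotide")
        dof = 40 * 4 - 4
        for j in (2, 3):
            t = model.beta[j] / model.beta_se[j]
            p = 2 * stats.t.sf(abs(t), dof)
            assert p > 0.05

    def test_out_of_window_observations_excluded(self):
        rng = np.random.default_rng(3)
        est = synth_estimates(REFERENCE_NUC.beta, rng, n_reps=2)
        bogus = CrossSectionEstimate(
            energy=1e5, thickness=100.0, gc_fraction=0.5,
            hits_nucleotide=10**6, hits_water=0, n_impacts=10**8,
            sigma_nuc_hat=1.0, sigma_h2o_hat=0.0,
            n_nucleotides_in_area=200, n_waters_in_area=0, sample_area=1.0,
        )
        m1 = fit_piecewise(est, response="nucleotide")
        m2 = fit_piecewise(est + [bogus], response="nucleotide")
        assert m1.beta == m2.beta

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(4)
        est = synth_estimates(REFERENCE_NUC.beta, rng, n_energies=3, n_reps=1)
        with pytest.raises(ValueError):
            fit_piecewise(est, response="nucleotide")

    def test_all_zero_counts_rejected(self):
        rng = np.random.default_rng(5)
        est = synth_estimates((-50.0, 0.0, 0.0, 0.0), rng, n_mol=1)
        with pytest.raises(ValueError, match="zero"):
            fit_piecewise(est, response="nucleotide")


class TestCovariateTest:
    def test_degrees_of_freedom_bookkeeping(self):
        # 33 energies x 5 thicknesses x 1 replicate = 165 observations,
        # 5 fitted parameters -> 160 residual dof
        rng = np.random.default_rng(6)
        est = synth_estimates(
            REFERENCE_NUC.beta, rng, n_energies=33, n_reps=1,
            thicknesses=[100.0, 1000.0, 1e4, 1e5, 1e6],
        )
        res = covariate_test(est, covariate="thickness", response="nucleotide")
        assert res.dof == 160
        assert res.tstat == pytest.approx(res.coefficient / res.stderr)

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_reps = 120
        for s in range(n_reps):
            rng = np.random.default_rng(1000 + s)
            est = synth_estimates(
                REFERENCE_NUC.beta, rng, n_energies=12, n_reps=1,
                thicknesses=[100.0, 1e3, 1e4, 1e5],
            )
            res = covariate_test(est, covariate="thickness", response="nucleotide")
            rejections += res.pvalue < 0.05
        # binomial(120, 0.05): mean 6, accept a generous 4-sigma band
        assert rejections <= 16

    def test_power_against_injected_thickness_effect(self):
        rng = np.random.default_rng(7)
        est = synth_estimates(
            REFERENCE_NUC.beta, rng, n_energies=12, n_reps=1,
            thicknesses=[100.0, 1e3, 1e4, 1e5],
            thickness_slope=2e-5,
        )
        res = covariate_test(est, covariate="thickness", response="nucleotide")
        assert res.pvalue < 0.05

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(8)
        est = synth_estimates(REFERENCE_NUC.beta, rng)
        with pytest.raises(ValueError, match="constant"):
            covariate_test(est, covariate="thickness", response="nucleotide")
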