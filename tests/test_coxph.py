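"""Weighted Cox estimation: oracles, invariances, and degenerate inputs."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

from gofsurv import (
    CoxEstimationError,
    SurvivalData,
    breslow_baseline,
    fit_coxph,
    wald_test,
    weighted_log_partial_likelihood,
)

from conftest import as_dataframe, make_survival_data


def _lifelines_fit(data, robust=True, ties="breslow"):
    cph = CoxPHFitter()
    cph.fit(
        as_dataframe(data),
        "time",
        "event",
        weights_col="w",
        robust=robust,
        show_progress=False,
        fit_options={"precision": 1e-9},
    )
    return cph


class TestDesignFormPartialLikelihood:
    def test_term_by_term_transcription(self):
        """5-subject toy data: value equals the displayed product evaluated literally."""
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        e = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
        x = np.array([[0.5], [-1.0], [0.2], [1.5], [0.0]])
        w = np.array([1.0, 2.0, 1.0, 1.0, 2.0])
        beta = np.array([0.3])
        expected = 0.0
        for i in range(5):
            if e[i] == 1:
                risk = t >= t[i]
                denom = np.sum(w[risk] * np.exp(x[risk, 0] * beta[0]))
                expected += np.log(w[i]) + beta[0] * x[i, 0] - np.log(denom)
        got = weighted_log_partial_likelihood(beta, SurvivalData(t, e, x, w))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unit_weights_reduce_to_unweighted_loglik(self):
        rng = np.random.default_rng(3)
        data = make_survival_data(rng, weighted=False)
        cph = _lifelines_fit(data, robust=False)
        ours = weighted_log_partial_likelihood(cph.params_.values, data)
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)

    def test_null_coef_no_ties_gives_log_risk_set_sizes(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, 0.0, 1.0, 0.0])
        data = SurvivalData(t, e, np.ones((4, 1)) * [[0.1], [0.2], [0.3], [0.4]])
        got = weighted_log_partial_likelihood(np.zeros(1), data)
        assert got == pytest.approx(-(np.log(4) + np.log(2)), rel=1e-12)


class TestFit:
    def test_one_dim_coef_matches_numeric_maximizer(self):
        """Newton solution equals an independent 1-d numeric optimizer."""
        rng = np.random.default_rng(5)
        data = make_survival_data(rng, n=30, p=1, weighted=False)
        fit = fit_coxph(data)

        def neg_pl(b):
            return -weighted_log_partial_likelihood(np.array([b]), data)

        opt = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(opt.x, abs=1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_established_weighted_cox(self, trial):
        """Coefficients and robust SEs agree with lifelines to 1e-4 relative."""
        rng = np.random.default_rng(100 + trial)
        data = make_survival_data(rng, n=rng.integers(20, 51), p=rng.integers(1, 4))
        fit = fit_coxph(data)
        cph = _lifelines_fit(data)
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-4, atol=1e-7)
        np.testing.assert_allclose(
            fit.se_robust, cph.standard_errors_.values, rtol=1e-4
        )

    def test_efron_ties_match_lifelines(self):
        rng = np.random.default_rng(8)
        data = make_survival_data(rng, n=40, p=2, weighted=False)
        data.time = np.round(data.time, 1)  # force ties
        fit = fit_coxph(data, ties_method="efron")
        cph = _lifelines_fit(data, robust=False)  # lifelines default is Efron
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-4)

    def test_constant_column_raises(self):
        rng = np.random.default_rng(1)
        data = make_survival_data(rng, n=20, p=2)
        data.covariates[:, 1] = 3.0
        with pytest.raises(CoxEstimationError, match="x1"):
            fit_coxph(data)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        data = make_survival_data(rng)
        fit1 = fit_coxph(data)
        data2 = SurvivalData(
            data.time, data.event, data.covariates, 2.0 * data.weights
        )
        fit2 = fit_coxph(data2)
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        data = make_survival_data(rng)
        perm = rng.permutation(data.n)
        fit1 = fit_coxph(data)
        fit2 = fit_coxph(
            SurvivalData(
                data.time[perm], data.event[perm], data.covariates[perm],
                data.weights[perm],
            )
        )
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-8)
        np.testing.assert_allclose(fit1.vcov_robust, fit2.vcov_robust, atol=1e-8)

    def test_vcov_symmetric_psd_and_score_small(self):
        rng = np.random.default_rng(9)
        data = make_survival_data(rng)
        fit = fit_coxph(data)
        assert fit.converged
        for V in (fit.vcov_model, fit.vcov_robust):
            np.testing.assert_allclose(V, V.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(V) > -1e-10)


class TestRobustVariance:
    def test_model_and_robust_agree_under_correct_iid_model(self):
        """With unit weights and a correctly specified model, sandwich ≈ inverse information."""
        rng = np.random.default_rng(12)
        n = 4000
        X = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-X @ [0.4, -0.2]))
        e = np.ones(n)
        fit = fit_coxph(SurvivalData(t, e, X))
        ratio = fit.se_robust / fit.se_model
        assert np.all(np.abs(ratio - 1) < 0.1)

    def test_degenerate_one_heavy_subject_does_not_crash(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1.0, 0.0, 0.0])
        x = np.array([[0.0], [1.0], [2.0]])
        w = np.array([100.0, 1e-6, 1e-6])
        fit = fit_coxph(SurvivalData(t, e, x, w))
        assert np.isfinite(fit.coef).all()


class TestWaldTest:
    def test_zero_coef_gives_p_one(self):
        rng = np.random.default_rng(2)
        data = make_survival_data(rng)
        fit = fit_coxph(data)
        fit.coef[0] = 0.0
        assert wald_test(fit, 0)["p_value"] == pytest.approx(1.0)

    def test_boundary_1p96_se(self):
        rng = np.random.default_rng(2)
        data = make_survival_data(rng)
        fit = fit_coxph(data)
        fit.coef[0] = 1.959963984540054 * fit.se_robust[0]
        res = wald_test(fit, 0)
        assert res["p_value"] == pytest.approx(0.05, abs=1e-6)
        assert res["ci_95"][0] == pytest.approx(0.0, abs=1e-9)

    def test_ci_endpoints_match_hand_computation(self):
        rng = np.random.default_rng(4)
        data = make_survival_data(rng, n=30, p=1, weighted=False)
        fit = fit_coxph(data)
        res = wald_test(fit, 0)
        se = fit.se_robust[0]
        assert res["ci_95"] == pytest.approx(
            (fit.coef[0] - 1.959963984540054 * se, fit.coef[0] + 1.959963984540054 * se)
        )


def test_breslow_baseline_matches_lifelines():
    rng = np.random.default_rng(15)
    data = make_survival_data(rng, n=60, p=2, weighted=False)
    fit = fit_coxph(data)
    times, ch = breslow_baseline(fit, data)
    cph = _lifelines_fit(data, robust=False)
    # lifelines reports the baseline at the covariate means; rescale ours
    scale = np.exp(data.covariates.mean(axis=0) @ fit.coef)
    ours_at = scale * ch[
        np.searchsorted(times, cph.baseline_cumulative_hazard_.index.to_numpy(),
                        side="right") - 1
    ]
    ref = cph.baseline_cumulative_hazard_.iloc[:, 0].to_numpy()
    keep = ref > 0
    np.testing.assert_allclose(ours_at[keep], ref[keep], rtol=1e-3)
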