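"""Logistic fitting, candidate catalog, stepwise selection, shrinkage."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from truthbench import (CandidateSpec, FittedLogistic, build_candidates,
                        fit_logistic, flip_coin_model, heuristic_shrinkage,
                        make_dataset, predict_risk, shrink_model,
                        stepwise_aic)
from truthbench.models import aic

LOG2 = float(np.log(2))


def _nll_oracle(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Direct likelihood maximisation, independent of the IRLS path."""
    M = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])

    def nll(beta):
        lp = M @ beta
        return float(np.sum(np.log1p(np.exp(-(2 * y - 1) * lp))))

    res = minimize(nll, np.zeros(M.shape[1]), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return res.x


class TestFitLogistic:
    def test_matches_direct_likelihood_oracle_on_small_fixtures(self, rng):
        for _ in range(5):
            n = 25
            X = pd.DataFrame({"a": rng.standard_normal(n),
                              "b": (rng.random(n) < 0.5).astype(float)})
            y = (rng.random(n) < expit(0.2 + 0.8 * X["a"] - 0.5 * X["b"])
                 ).astype(int)
            if not 0 < y.mean() < 1:
                continue
            fit = fit_logistic(X, y)
            if not fit.converged:     # separated fixture: capped, skip
                continue
            oracle = _nll_oracle(X, y)
            assert np.allclose(fit.coefficients, oracle, atol=1e-6)

    def test_intercept_only_closed_form(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.df_model == 0
        assert np.isclose(fit.coefficients[0], logit(0.3), atol=1e-8)
        assert abs(fit.train_lr_chi2) < 1e-8

    def test_parameter_recovery(self, rng):
        n = 12_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(LOG2 * x)).astype(int)
        fit = fit_logistic(pd.DataFrame({"x1": x}), y)
        p = expit(fit.coefficients[0] + fit.coefficients[1] * x)
        M = np.column_stack([np.ones(n), x])
        se = np.sqrt(np.diag(np.linalg.inv(M.T @ (M * (p * (1 - p))[:, None]))))
        assert abs(fit.coefficients[1] - LOG2) < 3 * se[1]
        assert fit.train_lr_chi2 > 0
        assert fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), np.array([1, 1]))

    def test_separation_capped_and_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])   # perfectly separated
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not fit.converged
        assert np.all(np.abs(fit.coefficients) <= 15.0)


class TestPredictRisk:
    def test_null_coefficients_give_half(self):
        model = FittedLogistic(("x",), np.zeros(2), 1, -1.0, -1.0)
        X = pd.DataFrame({"x": [-3.0, 0.0, 5.0]})
        ps = predict_risk(model, X)
        assert np.allclose(ps.p_hat, 0.5)

    def test_monotone_in_positive_coefficient(self):
        model = FittedLogistic(("x",), np.array([0.3, 1.2]), 1, -1.0, -1.0)
        X = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        ps = predict_risk(model, X)
        assert np.all(np.diff(ps.p_hat) > 0)

    def test_matches_bruteforce_expit_rows(self):
        model = FittedLogistic(("a", "b"), np.array([0.5, -1.0, 2.0]),
                               2, -1.0, -1.0)
        X = pd.DataFrame({"a": [0.0, 1.0, -1.0, 2.0, 0.5],
                          "b": [0.0, 0.5, 1.0, -1.0, 0.25]})
        expected = expit(0.5 - 1.0 * X["a"] + 2.0 * X["b"])
        ps = predict_risk(model, X)
        assert np.allclose(ps.p_hat, expected, atol=1e-12)

    def test_missing_column_named_in_error(self):
        model = FittedLogistic(("a", "zzz"), np.zeros(3), 2, -1.0, -1.0)
        with pytest.raises(KeyError, match="zzz"):
            predict_risk(model, pd.DataFrame({"a": [1.0]}))


class TestFlipCoin:
    def test_constant_half_brier_quarter(self, rng):
        for y in (np.array([0, 1, 1, 0, 1]), (rng.random(50) < 0.3).astype(int)):
            ps = flip_coin_model(y)
            assert np.all(ps.p_hat == 0.5)
            assert ps.model is None
            assert np.mean((ps.p_hat - y) ** 2) == 0.25

    def test_c_statistic_half(self, rng):
        from truthbench import c_statistic
        y = (rng.random(40) < 0.5).astype(int)
        ps = flip_coin_model(y)
        assert c_statistic(ps.p_hat, y) == 0.5


class TestStepwiseAIC:
    def test_strong_signal_kept_noise_dropped(self, uni_spec_small):
        spec = uni_spec_small
        kept_x1, dropped_noise = 0, 0
        for rep in range(5):
            ds = make_dataset(spec, rep)
            cand = CandidateSpec("AICTrueModel",
                                 variable_pool=("x1", "proxy_ind"),
                                 transform="stepAIC")
            fit = stepwise_aic(ds, cand)
            kept_x1 += "x1" in fit.variable_names
            dropped_noise += "proxy_ind" not in fit.variable_names
        assert kept_x1 == 5            # log(2) effect at n=480 is decisive
        assert dropped_noise >= 4      # AIC retains pure noise ~16% of runs

    def test_single_variable_pool_returned_unchanged(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        cand = CandidateSpec("only", variable_pool=("x1",),
                             transform="stepAIC")
        fit = stepwise_aic(ds, cand)
        assert fit.variable_names == ("x1",)

    def test_forced_out_never_included(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        cand = CandidateSpec("AICAddModel",
                             variable_pool=("x1", "proxy_ind", "proxy_c05"),
                             forced_out=("x1",), transform="stepAIC")
        fit = stepwise_aic(ds, cand)
        assert "x1" not in fit.variable_names

    def test_result_aic_not_worse_than_start(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 1)
        pool = ("x1", "proxy_ind", "proxy_c03", "proxy_c05", "proxy_c08")
        cand = CandidateSpec("AICTrueModel", variable_pool=pool,
                             transform="stepAIC")
        fit = stepwise_aic(ds, cand)
        from truthbench import fit_logistic as fl
        start = fl(ds.train_X[list(pool)], ds.train_y)
        assert aic(fit) <= aic(start) + 1e-9

    def test_empty_pool_rejected(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        with pytest.raises(ValueError):
            stepwise_aic(ds, CandidateSpec("bad", transform="stepAIC"))


class TestShrinkage:
    def test_factor_arithmetic(self):
        m = FittedLogistic(("a", "b"), np.zeros(3), 2,
                           train_loglik=-75.0, train_null_loglik=-100.0)
        assert np.isclose(heuristic_shrinkage(m), (50 - 2) / 50)  # 0.96
        m2 = FittedLogistic(("a",), np.zeros(2), 1,
                            train_loglik=-99.75, train_null_loglik=-100.0)
        assert np.isclose(heuristic_shrinkage(m2), -1.0)

    def test_factor_never_exceeds_one_and_nan_cases(self, rng):
        for chi2 in (0.01, 1.0, 10.0, 1e6):
            m = FittedLogistic(("a",), np.zeros(2), 1,
                               train_loglik=-100 + chi2 / 2,
                               train_null_loglik=-100.0)
            assert heuristic_shrinkage(m) <= 1.0
        assert np.isnan(heuristic_shrinkage(None))
        null = FittedLogistic((), np.zeros(1), 0, -100.0, -100.0)
        assert np.isnan(heuristic_shrinkage(null))

    def test_factor_grows_with_effect_size(self, rng):
        gammas = []
        for beta in (np.log(1.3), np.log(2), np.log(4)):
            vals = []
            for seed in range(4):
                r = np.random.default_rng(seed)
                x = r.standard_normal(2000)
                y = (r.random(2000) < expit(beta * x)).astype(int)
                vals.append(heuristic_shrinkage(
                    fit_logistic(pd.DataFrame({"x": x}), y)))
            gammas.append(np.mean(vals))
        assert gammas[0] < gammas[1] < gammas[2]

    def test_identity_limit_large_chi2(self, rng):
        x = rng.standard_normal(8000)
        y = (rng.random(8000) < expit(2.5 * x)).astype(int)
        X = pd.DataFrame({"x": x})
        fit = fit_logistic(X, y)
        shrunk = shrink_model(fit, X, y)
        assert heuristic_shrinkage(fit) > 0.99
        assert np.allclose(shrunk.coefficients, fit.coefficients, atol=5e-3)

    def test_zero_gamma_gives_constant_prevalence(self):
        # chi2 == df makes gamma exactly 0: slopes vanish, intercept refits
        m = FittedLogistic(("x",), np.array([0.4, 1.0]), 1,
                           train_loglik=-99.5, train_null_loglik=-100.0)
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.standard_normal(400)})
        y = (rng.random(400) < 0.3).astype(int)
        shrunk = shrink_model(m, X, y)
        assert shrunk.coefficients[1] == 0.0
        assert np.isclose(expit(shrunk.coefficients[0]), y.mean(), atol=1e-6)

    def test_shrunken_model_calibration_slope_moves_toward_one(self):
        # small-n overfit fixture: real signal plus noise terms, n=150
        from truthbench import logistic_recalibration
        deltas_raw, deltas_shrunk = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            Xtr = pd.DataFrame(r.standard_normal((150, 6)),
                               columns=[f"v{i}" for i in range(6)])
            Xte = pd.DataFrame(r.standard_normal((2000, 6)),
                               columns=Xtr.columns)
            coef = np.array([0.9, 0.6, 0.4, 0.0, 0.0, 0.0])
            ytr = (r.random(150) < expit(Xtr.to_numpy() @ coef)).astype(int)
            yte = (r.random(2000) < expit(Xte.to_numpy() @ coef)).astype(int)
            fit = fit_logistic(Xtr, ytr)
            if not fit.converged or not np.isfinite(heuristic_shrinkage(fit)):
                continue
            shrunk = shrink_model(fit, Xtr, ytr)
            for model, store in ((fit, deltas_raw), (shrunk, deltas_shrunk)):
                ps = predict_risk(model, Xte, yte)
                calib = logistic_recalibration(ps.p_hat, yte)
                store.append(abs(calib.b_hat - 1.0))
        assert np.mean(deltas_shrunk) < np.mean(deltas_raw)

    def test_undefined_gamma_returns_model_with_warning(self):
        m = FittedLogistic(("x",), np.array([0.0, 1.0]), 1, -100.0, -100.0)
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning, match="undefined"):
            out = shrink_model(m, X, y)
        assert out is m


class TestCandidateCatalog:
    def test_univariate_catalog_names(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        preds = build_candidates(ds)
        assert list(preds) == [
            "TrueModel", "FlipCoin", "AddIndModel", "Add03Model",
            "Add05Model", "Add08Model", "AICTrueModel", "ShrinkTrueModel",
            "AICAddModel", "ShrinkAddModel"]

    def test_multivariate_catalog_has_twelve_entries(self, multi_spec_small):
        ds = make_dataset(multi_spec_small, 0)
        preds = build_candidates(ds)
        assert len(preds) == 12
        assert preds["AICAddModel"] if "AICAddModel" in preds else True
        for name in ("TrueModel", "FlipCoin", "Variable1", "Variable2",
                     "AddIndCont", "AddCorrCont", "AddCat", "AddIndVar1",
                     "AddCorrVar1", "AddCorrVar2", "AddIndCorrVar1",
                     "AddIndCorrVar1AddCorrVar2"):
            assert name in preds

    def test_true_model_equals_direct_fit(self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        preds = build_candidates(ds)
        direct = predict_risk(
            fit_logistic(ds.train_X[["x1"]], ds.train_y),
            ds.test_X, ds.test_y)
        assert np.allclose(preds["TrueModel"].p_hat, direct.p_hat)

    def test_missing_proxy_column_raises_with_candidate_name(
            self, uni_spec_small):
        ds = make_dataset(uni_spec_small, 0)
        ds.train_X = ds.train_X.drop(columns=["proxy_c05"])
        ds.test_X = ds.test_X.drop(columns=["proxy_c05"])
        with pytest.raises(KeyError, match="Add05Model"):
            build_candidates(ds)

    def test_forced_in_out_overlap_rejected(self):
        with pytest.raises(ValueError):
            CandidateSpec("bad", forced_in=("a",), forced_out=("a",))
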