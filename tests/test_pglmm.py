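"""Penalized GLMM engine: oracle comparisons, shrinkage limits, diagnostics."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sbtindex import tweedie as tw
from sbtindex.pglmm import (FitError, ModelSpec, RankError, fit,
                            fit_tweedie_power, from_bundle, predict,
                            randomized_quantile_residuals, to_bundle,
                            wald_table)


def textbook_irls(y, X, offset, family, max_iter=200, tol=1e-12):
    """Independent unpenalized IRLS oracle for log-link GLMs.

    Plain Fisher scoring on the working response, written directly from the
    definition: w = mu^2 / V(mu), z = eta - offset + (y - mu)/mu.
    """
    vpow = {"gamma": 2.0, "poisson": 1.0}[family]
    beta = np.zeros(X.shape[1])
    mu = np.clip((y + y.mean()) / 2.0, 1e-8, None)
    eta = np.log(mu)
    for _ in range(max_iter):
        w = mu ** (2.0 - vpow)
        z = eta - offset + (y - mu) / mu
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
        eta = offset + X @ beta
        mu = np.exp(eta)
    return beta


def gamma_frame(rng, n=400, years=(1993, 1994, 1995)):
    df = pd.DataFrame({"year": rng.choice(years, n),
                       "sst": rng.normal(21.0, 1.5, n)})
    eta = 0.8 + 0.25 * (df["year"] - years[0]) + 0.3 * (df["sst"] - 21.0)
    df["y"] = rng.gamma(2.0, np.exp(eta) / 2.0)
    return df


class TestUnpenalizedAgainstOracle:
    @pytest.mark.parametrize("family", ["gamma", "poisson"])
    def test_coefficients_match_textbook_irls(self, family):
        rng = np.random.default_rng(2)
        df = gamma_frame(rng)
        if family == "poisson":
            df["y"] = rng.poisson(np.exp(0.5 + 0.3 * (df["sst"] - 21.0)))
            df = df[df["y"].ge(0)].reset_index(drop=True)
        spec = ModelSpec(family=family, response="y", fixed=("year",),
                         covariates=("sst",))
        m = fit(spec, df)
        X = np.column_stack([np.ones(len(df)),
                             (df["year"] == 1994).to_numpy(float),
                             (df["year"] == 1995).to_numpy(float),
                             df["sst"].to_numpy() - df["sst"].mean()])
        oracle = textbook_irls(df["y"].to_numpy(float), X, np.zeros(len(df)), family)
        np.testing.assert_allclose(m.coef_fixed().to_numpy(), oracle, atol=1e-6)


class TestShrinkageLimits:
    def _re_frame(self, rng, n=600):
        df = pd.DataFrame({"year": rng.choice([1993, 1994, 1995], n),
                           "month": rng.choice([1, 2, 3], n)})
        re = {(y, m): rng.normal(0, 0.5) for y in (1993, 1994, 1995)
              for m in (1, 2, 3)}
        eta = 1.0 + np.array([re[k] for k in zip(df["year"], df["month"])])
        df["y"] = rng.gamma(2.0, np.exp(eta) / 2.0)
        return df

    def test_heavy_penalty_shrinks_random_effects_to_zero(self):
        rng = np.random.default_rng(3)
        df = self._re_frame(rng)
        spec = ModelSpec(family="gamma", response="y", fixed=("year", "month"),
                         random=(("year", "month"),))
        norms = []
        for lam in (1e-2, 1e2, 1e6):
            m = fit(spec, df, fixed_lambdas={"year:month": lam})
            b = m.coef[m.info.n_fixed:]
            norms.append(float(np.linalg.norm(b)))
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_vanishing_penalty_recovers_fixed_interaction_glm(self):
        # lambda -> 0 on a small balanced design reproduces the GLM with the
        # interaction as a fixed effect (same fitted means)
        rng = np.random.default_rng(4)
        df = pd.DataFrame([(y, m) for y in (1993, 1994) for m in (1, 2)
                           for _ in range(40)], columns=["year", "month"])
        eta = {(1993, 1): 0.2, (1993, 2): 0.9, (1994, 1): 1.4, (1994, 2): 0.5}
        df["y"] = rng.gamma(4.0, np.exp([eta[k] for k in
                                         zip(df["year"], df["month"])]) / 4.0)
        spec = ModelSpec(family="gamma", response="y", fixed=("year", "month"),
                         random=(("year", "month"),))
        m = fit(spec, df, fixed_lambdas={"year:month": 1e-9})
        # the saturated fixed-effects fit reproduces cell means exactly
        cell_means = df.groupby(["year", "month"])["y"].transform("mean").to_numpy()
        np.testing.assert_allclose(m.fitted, cell_means, rtol=1e-4)

    def test_penalized_deviance_never_increases_within_irls(self):
        rng = np.random.default_rng(5)
        df = self._re_frame(rng)
        spec = ModelSpec(family="gamma", response="y", fixed=("year", "month"),
                         random=(("year", "month"),))
        m = fit(spec, df)
        by_outer: dict[int, list[float]] = {}
        for outer, _, pdev in m.irls_trace:
            by_outer.setdefault(outer, []).append(pdev)
        for seq in by_outer.values():
            assert all(b <= a * (1 + 1e-10) for a, b in zip(seq, seq[1:]))


class TestTweediePower:
    def test_power_and_dispersion_recovered_from_cpg_simulation(self):
        rng = np.random.default_rng(6)
        n = 3000
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        mu = np.exp(0.3 + 0.4 * df["x"].to_numpy())
        df["y"] = tw.sample_cpg(rng, mu, 1.78, 1.13)
        spec = ModelSpec(family="tweedie", response="y", covariates=("x",))
        m = fit_tweedie_power(spec, df)
        assert m.var_power == pytest.approx(1.13, abs=0.05)
        assert m.phi == pytest.approx(1.78, abs=0.15)

    def test_pure_poisson_pushes_power_to_lower_boundary(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.poisson(1.5, 2000).astype(float)})
        m = fit_tweedie_power(ModelSpec(family="tweedie", response="y"), df,
                              refine=True)
        assert m.var_power <= 1.05

    def test_no_zero_response_is_rejected(self):
        df = pd.DataFrame({"y": np.full(50, 2.0)})
        with pytest.raises(ValueError, match="no zeros"):
            fit_tweedie_power(ModelSpec(family="tweedie", response="y"), df)

    def test_all_zero_response_is_rejected(self):
        df = pd.DataFrame({"y": np.zeros(50)})
        with pytest.raises(ValueError):
            fit_tweedie_power(ModelSpec(family="tweedie", response="y"), df)

    def test_poisson_fit_flags_overdispersion(self):
        # negative-binomial-style counts: Pearson dispersion well above 1,
        # which is what motivates the Tweedie family for the cell counts
        rng = np.random.default_rng(8)
        lam = rng.gamma(1.0, 2.0, 1500)
        df = pd.DataFrame({"y": rng.poisson(lam).astype(float)})
        m = fit(ModelSpec(family="poisson", response="y"), df)
        assert m.phi > 1.5


class TestPredictAndWald:
    def test_prediction_at_training_rows_equals_fitted(self):
        rng = np.random.default_rng(9)
        df = gamma_frame(rng, n=200)
        spec = ModelSpec(family="gamma", response="y", fixed=("year",),
                         covariates=("sst",))
        m = fit(spec, df)
        mu, se = predict(m, df)
        np.testing.assert_allclose(mu, m.fitted, rtol=1e-10)
        assert np.all(se > 0)

    def test_distance_offset_scales_prediction_proportionally(self):
        rng = np.random.default_rng(10)
        n = 500
        df = pd.DataFrame({"log_dist": np.log(rng.uniform(20, 60, n))})
        mu = np.exp(df["log_dist"].to_numpy() + np.log(0.02))
        df["y"] = tw.sample_cpg(rng, mu, 1.3, 1.4)
        spec = ModelSpec(family="tweedie", response="y", offsets=("log_dist",),
                         var_power=1.4)
        m = fit(spec, df)
        nd1 = pd.DataFrame({"log_dist": [np.log(100.0)]})
        nd2 = pd.DataFrame({"log_dist": [np.log(200.0)]})
        mu1, _ = predict(m, nd1)
        mu2, _ = predict(m, nd2)
        assert mu2[0] == pytest.approx(2.0 * mu1[0], rel=1e-10)
        # the per-100-nm convention: offset log(100) turns the intercept rate
        # into a rate per 100 nm of effort
        assert mu1[0] == pytest.approx(100.0 * np.exp(m.coef[0]), rel=1e-10)

    def test_unseen_factor_level_is_an_error(self):
        rng = np.random.default_rng(11)
        df = gamma_frame(rng, n=100)
        m = fit(ModelSpec(family="gamma", response="y", fixed=("year",)), df)
        with pytest.raises(ValueError, match="unseen"):
            predict(m, pd.DataFrame({"year": [2009]}))

    def test_constant_covariate_raises_rank_error(self):
        rng = np.random.default_rng(12)
        df = gamma_frame(rng, n=100)
        df["sst"] = 20.0
        with pytest.raises(RankError, match="sst"):
            fit(ModelSpec(family="gamma", response="y", fixed=("year",),
                          covariates=("sst",)), df)

    def test_wald_table_is_estimate_over_se_with_normal_p(self):
        rng = np.random.default_rng(13)
        m = fit(ModelSpec(family="gamma", response="y", fixed=("year",),
                          covariates=("sst",)), gamma_frame(rng))
        wt = wald_table(m)
        np.testing.assert_allclose(wt["z"], wt["estimate"] / wt["se"])
        np.testing.assert_allclose(wt["p"], 2 * stats.norm.sf(np.abs(wt["z"])))
        # the reported scale: an estimate of 0.326 with SE 0.054 must print
        # a z-statistic of about 6.0
        row = wt.set_index("term").loc["sst"]
        assert row["estimate"] / row["se"] == pytest.approx(row["z"])

    def test_prediction_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(14)
        ses = {}
        for n in (200, 2000):
            df = gamma_frame(rng, n=n)
            m = fit(ModelSpec(family="gamma", response="y", fixed=("year",),
                              covariates=("sst",)), df)
            _, se = predict(m, df.iloc[:100])
            ses[n] = np.median(se)
        assert ses[200] / ses[2000] > 1.0


class TestQuantileResiduals:
    def test_uniform_under_correct_model(self):
        # calibration study: KS uniformity should hold in nearly all replicates
        rng = np.random.default_rng(15)
        n, ok = 120, 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame({"x": rng.normal(0, 1, n)})
            df["y"] = rng.gamma(2.0, np.exp(1.0 + 0.5 * df["x"]) / 2.0)
            m = fit(ModelSpec(family="gamma", response="y", covariates=("x",)), df)
            r = randomized_quantile_residuals(m, seed=rng)
            if stats.kstest(r, "uniform").pvalue > 0.01:
                ok += 1
        assert ok >= 95

    def test_omitted_covariate_leaves_residual_pattern(self):
        rng = np.random.default_rng(16)
        n = 800
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["y"] = rng.gamma(2.0, np.exp(1.0 + 0.8 * df["x"]) / 2.0)
        m = fit(ModelSpec(family="gamma", response="y"), df)  # x omitted
        r = randomized_quantile_residuals(m, seed=17)
        rho, p = stats.spearmanr(r, df["x"])
        assert p < 0.01 and rho > 0.3

    def test_single_draw_residuals_stay_in_open_interval(self):
        rng = np.random.default_rng(18)
        df = gamma_frame(rng, n=60)
        m = fit(ModelSpec(family="gamma", response="y"), df)
        r = randomized_quantile_residuals(m, seed=1, n_sim=1)
        assert np.all((r > 0) & (r < 1))


class TestBundle:
    def test_json_round_trip_preserves_predictions(self, sim, pipeline_result):
        m = pipeline_result.bps_model
        back = from_bundle(json.loads(json.dumps(to_bundle(m), default=lambda o:
                                                 o.item() if hasattr(o, "item")
                                                 else list(o))))
        nd = pd.DataFrame({"year": [1994], "month": [2], "area": [3],
                           "sst": [20.5]})
        mu0, se0 = predict(m, nd)
        mu1, se1 = predict(back, nd)
        assert mu1[0] == pytest.approx(mu0[0], rel=1e-12)
        assert se1[0] == pytest.approx(se0[0], rel=1e-12)
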