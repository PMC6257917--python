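"""Index assembly, normalization contracts, and variance propagation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sbtindex.index import (ReferenceConditions, StratumPrediction,
                            annual_index, make_annual_predictor,
                            qualitative_trend, standardized_predictions)
from sbtindex.pglmm import predict
from sbtindex.survey_data import AreaWeights, SurveyStratum
from sbtindex.uncertainty import (VarianceDecomposition, conditional_variance,
                                  confidence_intervals, environmental_variance,
                                  index_with_uncertainty)


def make_pred(year, area=1, b=10.0, s=1.0, se_b=0.0, se_s=0.0, month=1):
    return StratumPrediction(stratum=SurveyStratum(year, month, area),
                             b_hat=b, s_hat=s, se_log_b=se_b, se_log_s=se_s,
                             dlogb_dgamma=np.zeros(1), dlogs_dgamma=np.zeros(1))


class TestAnnualIndex:
    def test_three_to_one_ratio_normalizes_to_15_05(self):
        preds = [make_pred(1993, b=3.0, s=1.0), make_pred(1994, b=1.0, s=1.0)]
        out = annual_index(preds, AreaWeights({1: 1.0}))
        np.testing.assert_allclose(out["I_hat"], [1.5, 0.5])

    def test_single_stratum_year_is_weighted_product(self):
        preds = [make_pred(1993, area=2, b=4.0, s=2.5),
                 make_pred(1994, area=2, b=4.0, s=2.5)]
        w = AreaWeights({1: 0.7, 2: 0.3})
        out = annual_index(preds, w)
        assert out["A_hat"].iloc[0] == pytest.approx(0.3 * 10.0)

    def test_matches_brute_force_double_loop(self, pipeline_result, reduced_config):
        preds = pipeline_result.predictions
        w = reduced_config.area_weights
        out = annual_index(preds, w).set_index("year")
        for year in out.index:
            total = 0.0
            for p in preds:
                if p.stratum.year == year:
                    total += w[p.stratum.area] * p.s_hat * p.b_hat
            assert out.loc[year, "A_hat"] == pytest.approx(total, rel=1e-12)

    def test_missing_weight_is_an_error(self):
        with pytest.raises(ValueError, match="weight"):
            annual_index([make_pred(1993, area=7)], AreaWeights({1: 1.0}))

    def test_mean_one_to_1e9(self, pipeline_result):
        assert pipeline_result.index["I_hat"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_relative_index(self, pipeline_result, reduced_config):
        # multiplying every B (or S) by a constant cannot move the index
        preds = pipeline_result.predictions
        w = reduced_config.area_weights
        base = annual_index(preds, w)
        scaled = [StratumPrediction(p.stratum, p.b_hat * 7.3, p.s_hat,
                                    p.se_log_b, p.se_log_s,
                                    p.dlogb_dgamma, p.dlogs_dgamma)
                  for p in preds]
        out = annual_index(scaled, w)
        np.testing.assert_allclose(out["I_hat"], base["I_hat"], rtol=1e-12)

    def test_product_consistency(self, pipeline_result):
        for p in pipeline_result.predictions:
            assert p.a_hat == pytest.approx(p.b_hat * p.s_hat, rel=1e-12)


class TestStandardizedPredictions:
    def test_sst_shift_scales_biomass_by_exp_gamma_delta(self, pipeline_result):
        bps, spm = pipeline_result.bps_model, pipeline_result.spm_model
        ref = pipeline_result.reference
        strata = [p.stratum for p in pipeline_result.predictions[:10]]
        base = standardized_predictions(bps, spm, ref, strata)
        delta = 1.5
        shifted_ref = ReferenceConditions(env={**ref.env,
                                               "sst": ref.env["sst"] + delta})
        shifted = standardized_predictions(bps, spm, shifted_ref, strata)
        gamma = bps.covariate_estimates()["sst"]
        for p0, p1 in zip(base, shifted):
            assert p1.b_hat / p0.b_hat == pytest.approx(np.exp(gamma * delta),
                                                        rel=1e-9)

    def test_unseen_stratum_is_an_error(self, pipeline_result):
        with pytest.raises(ValueError, match="unseen"):
            standardized_predictions(pipeline_result.bps_model,
                                     pipeline_result.spm_model,
                                     pipeline_result.reference,
                                     [SurveyStratum(2009, 1, 1)])

    def test_split_variance_reassembles_full_prediction_variance(self, pipeline_result):
        # conditional variance + gamma quadratic form == the full joint
        # quadratic form, exactly, in linear-predictor space
        bps = pipeline_result.bps_model
        p = pipeline_result.predictions[3]
        nd = pd.DataFrame({"year": [p.stratum.year], "month": [p.stratum.month],
                           "area": [p.stratum.area],
                           "sst": [pipeline_result.reference.env["sst"]]})
        _, se_full = predict(bps, nd)
        vg = bps.covariate_cov().to_numpy()
        v_split = p.se_log_b ** 2 + float(p.dlogb_dgamma @ vg @ p.dlogb_dgamma)
        assert v_split == pytest.approx(se_full[0] ** 2, rel=1e-8)


class TestConditionalVariance:
    def test_forced_delta_method_example(self):
        pred = make_pred(1993, b=5.0, s=2.0, se_b=0.1, se_s=0.2)
        out = conditional_variance([pred], AreaWeights({1: 1.0}))
        assert out["v_cond"].iloc[0] == pytest.approx(100.0 * 0.05)

    def test_zero_se_gives_zero_variance(self):
        out = conditional_variance([make_pred(1993)], AreaWeights({1: 1.0}))
        assert out["v_cond"].iloc[0] == 0.0

    def test_weights_enter_squared(self):
        pred = make_pred(1993, area=1, b=5.0, s=2.0, se_b=0.1, se_s=0.2)
        v1 = conditional_variance([pred], AreaWeights({1: 1.0}))["v_cond"].iloc[0]
        pred2 = make_pred(1993, area=1, b=5.0, s=2.0, se_b=0.1, se_s=0.2)
        w = AreaWeights({1: 0.5, 2: 0.5})
        v2 = conditional_variance([pred2], w)["v_cond"].iloc[0]
        assert v2 == pytest.approx(0.25 * v1)


class TestEnvironmentalVariance:
    def test_matches_closed_form_gradient(self):
        # A(gamma) = c * exp(gamma * s): dA/dgamma = s * A exactly
        c, s, gamma = 4.0, 1.7, 0.3

        def annual_fn(delta):
            return np.array([c * np.exp((gamma + delta[0]) * s)])

        v, grads = environmental_variance(annual_fn, np.array([gamma]),
                                          np.array([[0.04]]))
        a = c * np.exp(gamma * s)
        assert grads[0, 0] == pytest.approx(s * a, rel=1e-6)
        assert v[0] == pytest.approx((s * a) ** 2 * 0.04, rel=1e-6)

    def test_zero_coefficient_covariance_gives_zero(self):
        def annual_fn(delta):
            return np.array([np.exp(delta[0])])
        v, _ = environmental_variance(annual_fn, np.zeros(1), np.zeros((1, 1)))
        assert v[0] == 0.0

    def test_quadratic_in_coefficient_uncertainty(self):
        def annual_fn(delta):
            return np.array([np.exp(0.5 * delta[0] + 0.2 * delta[1])])
        g = np.array([0.3])
        v1, _ = environmental_variance(annual_fn, np.zeros(2), np.eye(2) * 0.04)
        v2, _ = environmental_variance(annual_fn, np.zeros(2), np.eye(2) * 0.01)
        assert v1[0] == pytest.approx(4.0 * v2[0], rel=1e-6)

    def test_negative_variance_parts_rejected(self):
        with pytest.raises(ValueError):
            VarianceDecomposition(years=np.array([1993]),
                                  v_cond=np.array([-1.0]),
                                  v_env=np.array([0.0]),
                                  gradients=np.zeros((1, 1)))


class TestConfidenceIntervals:
    def test_cv_point_two_gives_0676_1480(self):
        out = confidence_intervals(np.array([1.0]), np.array([0.04]))
        assert out["cv"].iloc[0] == pytest.approx(0.2)
        assert out["lo95"].iloc[0] == pytest.approx(0.676, abs=5e-4)
        assert out["hi95"].iloc[0] == pytest.approx(1.480, abs=5e-4)

    def test_zero_variance_collapses_to_point(self):
        out = confidence_intervals(np.array([3.0]), np.array([0.0]))
        assert out["lo95"].iloc[0] == out["hi95"].iloc[0] == 3.0

    def test_equivariance_under_scaling(self):
        a, v, c = np.array([2.0]), np.array([0.25]), 5.0
        base = confidence_intervals(a, v)
        scaled = confidence_intervals(c * a, c ** 2 * v)
        assert scaled["lo95"].iloc[0] == pytest.approx(c * base["lo95"].iloc[0])
        assert scaled["hi95"].iloc[0] == pytest.approx(c * base["hi95"].iloc[0])

    def test_nonpositive_estimate_rejected(self):
        with pytest.raises(ValueError):
            confidence_intervals(np.array([0.0]), np.array([1.0]))

    def test_full_series_bounds_bracket_point(self, pipeline_result):
        idx = pipeline_result.index
        assert ((idx["lo95"] < idx["A_hat"]) & (idx["A_hat"] < idx["hi95"])).all()
        assert (idx["lo95"] > 0).all()


class TestTrend:
    def test_flat_series_gives_ratio_one(self):
        idx = pd.DataFrame({"year": [1993, 1994, 1995, 1996, 1997],
                            "I_hat": np.ones(5)})
        assert qualitative_trend(idx)["ratio"] == pytest.approx(1.0)

    def test_engineered_four_fold_drop(self):
        idx = pd.DataFrame({"year": range(1993, 2001),
                            "I_hat": [2.0] * 4 + [0.5] * 4})
        out = qualitative_trend(idx, n_early=4)
        assert out["ratio"] == pytest.approx(4.0)
        assert out["early_years"] == [1993, 1994, 1995, 1996]
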