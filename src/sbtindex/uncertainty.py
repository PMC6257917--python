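"""Variance of the annual abundance estimates: conditional + environmental.

Uncertainty in the environmental coefficients makes the stratum estimates
dependent (an error in the SST effect moves every stratum together), so the
annual variance is assembled in two parts:

1. *Conditional* variance — given the environmental coefficients the stratum
   predictions come from independent pieces of survey effort, so the
   variance of the area-weighted sum is the weighted sum of the stratum
   variances: V_cond(i) = sum_jk w_k^2 Var(A_ijk), with each stratum's
   Var(A) from the delta method on the two components' linear-predictor SEs.

2. *Environmental* variance — the numerical gradient of each annual total
   with respect to the stacked environmental coefficient vector, pushed
   through the coefficient covariance by the chain rule:
   V_env(i) = g_i' Cov(gamma_hat) g_i.  The BpS and SpM blocks are fit to
   different responses and treated as independent.

V_total = V_cond + V_env.  CV = sqrt(V)/A, and 95% intervals assume the log
estimate is normal with SD approximated by the CV:
exp(log A +/- 1.96 * CV).  Uncertainty in the pair-efficiency offsets is
deliberately not propagated (they enter the count model as known offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .index import StratumPrediction, make_annual_predictor
from .survey_data import AreaWeights

__all__ = [
    "VarianceDecomposition",
    "conditional_variance",
    "environmental_variance",
    "confidence_intervals",
    "index_with_uncertainty",
]


@dataclass
class VarianceDecomposition:
    """Per-year variance parts and the gradient records behind V_env."""

    years: np.ndarray
    v_cond: np.ndarray
    v_env: np.ndarray
    gradients: np.ndarray  # (n_years, n_gamma): dA_i / d gamma_m

    def __post_init__(self):
        if np.any(self.v_cond < 0) or np.any(self.v_env < 0):
            raise ValueError("variance components must be nonnegative")

    @property
    def v_total(self) -> np.ndarray:
        return self.v_cond + self.v_env

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "v_cond": self.v_cond,
                             "v_env": self.v_env, "v_total": self.v_total})


def conditional_variance(preds: list[StratumPrediction], w: AreaWeights,
                         cond_cov: dict[str, np.ndarray] | None = None
                         ) -> pd.DataFrame:
    """Per-year conditional variance of the area-weighted annual total.

    With ``cond_cov`` (the cross-stratum conditional covariances of the two
    linear predictors, from ``standardized_predictions(..., with_cov=True)``)
    the full delta method is used:
    V_cond(i) = a_i' (Cov_logB + Cov_logS) a_i with a_i = w_k A_ijk restricted
    to year i.  Stratum predictions within a year share the estimated year
    effect (and intercept), so the off-diagonal terms matter.  Without
    ``cond_cov`` the strata are treated as independent (diagonal only):
    V_cond(i) = sum_jk w_k^2 A_ijk^2 (CV_B^2 + CV_S^2).
    """
    for p in preds:
        if not (np.isfinite(p.se_log_b) and np.isfinite(p.se_log_s)):
            raise ValueError(f"stratum {p.stratum}: missing prediction SE")
    years = sorted({p.stratum.year for p in preds})
    if cond_cov is None:
        acc = {y: 0.0 for y in years}
        for p in preds:
            acc[p.stratum.year] += w[p.stratum.area] ** 2 * p.var_a_conditional
        return pd.DataFrame({"year": years, "v_cond": [acc[y] for y in years]})

    total = cond_cov["bps"] + cond_cov["spm"]
    a = np.array([w[p.stratum.area] * p.a_hat for p in preds])
    v = []
    for y in years:
        mask = np.array([p.stratum.year == y for p in preds])
        ay = np.where(mask, a, 0.0)
        v.append(max(float(ay @ total @ ay), 0.0))
    return pd.DataFrame({"year": years, "v_cond": v})


def environmental_variance(annual_fn, gamma_hat: np.ndarray,
                           cov_gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """V_env per year by central differences and the chain rule.

    ``annual_fn(delta)`` evaluates the per-year annual totals at the
    environmental coefficient vector ``gamma_hat + delta`` (prediction-only
    re-evaluation).  Steps are h_m = max(1e-4, 1e-3 |gamma_m|).  Returns
    ``(v_env, gradients)``.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    m = gamma_hat.size
    cov_gamma = np.asarray(cov_gamma, dtype=float)
    if cov_gamma.shape != (m, m):
        raise ValueError(f"cov_gamma must be {m}x{m}")
    base = annual_fn(np.zeros(m))
    grads = np.zeros((base.size, m))
    for j in range(m):
        h = max(1e-4, 1e-3 * abs(gamma_hat[j]))
        e = np.zeros(m)
        e[j] = h
        hi, lo = annual_fn(e), annual_fn(-e)
        g = (hi - lo) / (2.0 * h)
        if not np.all(np.isfinite(g)):
            raise ValueError(f"non-finite derivative for coefficient index {j}")
        grads[:, j] = g
    v_env = np.einsum("im,mn,in->i", grads, cov_gamma, grads)
    return np.maximum(v_env, 0.0), grads


def confidence_intervals(a: np.ndarray, v_total: np.ndarray,
                         level_z: float = 1.96) -> pd.DataFrame:
    """CV and lognormal confidence bounds: exp(log A +/- z * sqrt(V)/A)."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(v_total, dtype=float)
    if np.any(a <= 0):
        raise ValueError("annual estimates must be positive")
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    cv = np.sqrt(v) / a
    lo = a * np.exp(-level_z * cv)
    hi = a * np.exp(level_z * cv)
    return pd.DataFrame({"cv": cv, "lo95": lo, "hi95": hi})


def index_with_uncertainty(preds: list[StratumPrediction], w: AreaWeights,
                           bps_model, spm_model,
                           cond_cov: dict[str, np.ndarray] | None = None
                           ) -> tuple[pd.DataFrame, VarianceDecomposition]:
    """Assemble the full annual index series with CVs and 95% intervals.

    The mean-one normalisation is treated as a fixed rescale, so the CVs of
    A_i attach unchanged to I_i (the covariance between years induced by the
    shared mean is not propagated — intervals are reported per year).
    """
    cond = conditional_variance(preds, w, cond_cov=cond_cov)
    gamma_b = bps_model.covariate_estimates().to_numpy()
    gamma_s = spm_model.covariate_estimates().to_numpy()
    gamma_hat = np.concatenate([gamma_b, gamma_s])
    cov = sla.block_diag(bps_model.covariate_cov().to_numpy(),
                         spm_model.covariate_cov().to_numpy())
    annual_fn, years = make_annual_predictor(preds, w, n_bps_gamma=gamma_b.size)
    a_hat = annual_fn(np.zeros(gamma_hat.size))
    v_env, grads = environmental_variance(annual_fn, gamma_hat, cov)
    assert np.array_equal(years, cond["year"].to_numpy())

    decomp = VarianceDecomposition(years=years, v_cond=cond["v_cond"].to_numpy(),
                                   v_env=v_env, gradients=grads)
    ci = confidence_intervals(a_hat, decomp.v_total)
    out = pd.DataFrame({"year": years, "A_hat": a_hat})
    out["I_hat"] = out["A_hat"] / out["A_hat"].mean()
    out = pd.concat([out, ci], axis=1)
    # bounds on the index scale, same fixed rescale as the point estimates
    scale = out["I_hat"] / out["A_hat"]
    out["I_lo95"] = out["lo95"] * scale
    out["I_hi95"] = out["hi95"] * scale
    return out, decomp
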