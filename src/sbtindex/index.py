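"""Standardized stratum predictions and the area-weighted annual index.

Each year:month:area stratum gets a conditional (random effects included)
prediction of biomass per sighting (B) at reference SST and of sightings per
100 nm (S) at reference conditions, best pair (Obs = 1) and 100 nm of
effort.  Stratum abundance is the product A = S * B; the annual estimate is
the area-weighted sum over months and areas, and the final index divides the
annual estimates by their mean so the series averages exactly one — a
*relative* index: rescaling either component, the reference conditions, or
the reference distance shifts every year identically and cancels.

Prediction uncertainty is split for downstream variance propagation: the
*conditional* SE of each stratum's linear predictor given the environmental
coefficients, plus the *sensitivity* of the linear predictor to those
coefficients (which includes the induced shift of the stratum effects,
computed from the joint penalized covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pglmm import FittedComponentModel, build_design
from .survey_data import AreaWeights, SurveyStratum

__all__ = [
    "ReferenceConditions",
    "StratumPrediction",
    "standardized_predictions",
    "annual_index",
    "make_annual_predictor",
    "qualitative_trend",
]


@dataclass
class ReferenceConditions:
    """The 'standard survey': reference covariates, best pair, 100 nm of effort."""

    env: dict[str, float]
    distance_nm: float = 100.0  # so S is a per-100-nm rate

    @classmethod
    def from_effort(cls, cells: pd.DataFrame,
                    env_columns=("sst", "wind", "haze", "swell", "shadow"),
                    distance_nm: float = 100.0) -> "ReferenceConditions":
        """Average conditions over all effort records pooled across years."""
        env = {c: float(cells[c].mean()) for c in env_columns if c in cells.columns}
        return cls(env=env, distance_nm=distance_nm)


@dataclass
class StratumPrediction:
    """Standardized B, S and A = S*B for one stratum, with conditional SEs."""

    stratum: SurveyStratum
    b_hat: float
    s_hat: float
    se_log_b: float          # conditional SE of log B given env coefficients
    se_log_s: float
    dlogb_dgamma: np.ndarray = field(repr=False)  # sensitivity to BpS env coefs
    dlogs_dgamma: np.ndarray = field(repr=False)  # sensitivity to SpM env coefs

    @property
    def a_hat(self) -> float:
        return self.b_hat * self.s_hat

    @property
    def var_a_conditional(self) -> float:
        """Delta-method variance of A given the env coefficients.

        B and S come from models fit to different responses, so conditional
        on the environmental coefficients they are treated as independent:
        Var(A) = A^2 (CV_B^2 + CV_S^2) with CVs taken as linear-predictor SEs.
        """
        return self.a_hat ** 2 * (self.se_log_b ** 2 + self.se_log_s ** 2)


def _partitioned_prediction(model: FittedComponentModel, newdata: pd.DataFrame):
    """Per-row (eta, conditional covariance of eta, sensitivity to gamma).

    Partition the coefficients into the environmental block gamma and the
    rest u.  Conditional on gamma, Cov(eta) uses the conditional covariance
    V_uu - V_ug V_gg^-1 V_gu — the full cross-stratum matrix, because strata
    share year/month/area effects and the intercept; the sensitivity to gamma
    is the direct design contribution plus the induced shift of E[u | gamma]:
    d eta / d gamma = c_gamma + (c_u' V_ug) V_gg^-1.
    """
    X, Z, offset, _ = build_design(model.spec, newdata, info=model.info)
    C = sp.hstack([sp.csr_matrix(X), Z], format="csr").toarray()
    eta = offset + C @ model.coef

    names = model.info.colnames_fixed
    g_idx = np.array([names.index(c) for c in model.spec.covariates], dtype=int)
    all_idx = np.arange(C.shape[1])
    u_idx = np.setdiff1d(all_idx, g_idx)

    V = model.cov
    if len(g_idx) == 0:
        cov_eta = C @ V @ C.T
        return eta, cov_eta, np.zeros((len(eta), 0))

    Vgg = V[np.ix_(g_idx, g_idx)]
    Vug = V[np.ix_(u_idx, g_idx)]
    Vuu = V[np.ix_(u_idx, u_idx)]
    Vgg_inv = np.linalg.inv(Vgg)
    Vcond = Vuu - Vug @ Vgg_inv @ Vug.T

    Cu = C[:, u_idx]
    Cg = C[:, g_idx]
    cov_eta = Cu @ Vcond @ Cu.T
    sens = Cg + (Cu @ Vug) @ Vgg_inv
    return eta, cov_eta, sens


def standardized_predictions(bps: FittedComponentModel, spm: FittedComponentModel,
                             ref: ReferenceConditions,
                             strata: list[SurveyStratum],
                             with_cov: bool = False):
    """Conditional standardized predictions for every requested stratum.

    Both models are evaluated at the reference covariates; the SpM offsets
    are fixed at log(ref.distance_nm) and log(1) (the best pair), so S is a
    per-100-nm rate under standard conditions.  Strata must use year, month
    and area levels seen in training.

    With ``with_cov=True`` also returns the full cross-stratum conditional
    covariance of the linear predictors, ``{"bps": ..., "spm": ...}`` — the
    stratum predictions are NOT independent (they share year, month and area
    effects), and annual variances need the off-diagonal terms.
    """
    rows = pd.DataFrame([{"year": s.year, "month": s.month, "area": s.area}
                         for s in strata])
    bps_nd = rows.copy()
    for c in bps.spec.covariates:
        if c not in ref.env:
            raise ValueError(f"reference conditions lack covariate {c!r}")
        bps_nd[c] = ref.env[c]
    eta_b, cov_b, sens_b = _partitioned_prediction(bps, bps_nd)

    spm_nd = rows.copy()
    for c in spm.spec.covariates:
        if c not in ref.env:
            raise ValueError(f"reference conditions lack covariate {c!r}")
        spm_nd[c] = ref.env[c]
    spm_nd["log_dist"] = np.log(ref.distance_nm)
    spm_nd["log_obs"] = 0.0
    eta_s, cov_s, sens_s = _partitioned_prediction(spm, spm_nd)

    se_b = np.sqrt(np.maximum(np.diag(cov_b), 0.0))
    se_s = np.sqrt(np.maximum(np.diag(cov_s), 0.0))
    preds = [StratumPrediction(stratum=s,
                               b_hat=float(np.exp(eta_b[i])),
                               s_hat=float(np.exp(eta_s[i])),
                               se_log_b=float(se_b[i]),
                               se_log_s=float(se_s[i]),
                               dlogb_dgamma=sens_b[i],
                               dlogs_dgamma=sens_s[i])
             for i, s in enumerate(strata)]
    if with_cov:
        return preds, {"bps": cov_b, "spm": cov_s}
    return preds


def annual_index(preds: list[StratumPrediction], w: AreaWeights) -> pd.DataFrame:
    """Area-weighted annual totals and the mean-one index (point estimates).

    A_i = sum_j sum_k w_k * S_hat_ijk * B_hat_ijk;  I_i = A_i / mean(A).
    """
    missing = sorted({p.stratum.area for p in preds} - set(w.w))
    if missing:
        raise ValueError(f"no area weight for areas {missing}")
    acc: dict[int, float] = {}
    for p in preds:
        acc[p.stratum.year] = acc.get(p.stratum.year, 0.0) + w[p.stratum.area] * p.a_hat
    out = pd.DataFrame({"year": sorted(acc), "A_hat": [acc[y] for y in sorted(acc)]})
    out["I_hat"] = out["A_hat"] / out["A_hat"].mean()
    return out


def make_annual_predictor(preds: list[StratumPrediction], w: AreaWeights,
                          n_bps_gamma: int):
    """Build A(gamma) for variance propagation — prediction-only, no refit.

    Returns ``(annual_fn, gamma_dim)`` where ``annual_fn(delta)`` maps a
    perturbation of the stacked environmental coefficient vector
    (BpS block first, then SpM block) to the per-year annual totals, using
    each stratum's stored linear-predictor sensitivities.
    """
    years = sorted({p.stratum.year for p in preds})
    yi = {y: i for i, y in enumerate(years)}
    gamma_dim = n_bps_gamma + (len(preds[0].dlogs_dgamma) if preds else 0)

    def annual_fn(delta: np.ndarray) -> np.ndarray:
        delta = np.asarray(delta, dtype=float)
        if delta.shape != (gamma_dim,):
            raise ValueError(f"expected perturbation of length {gamma_dim}")
        d_b, d_s = delta[:n_bps_gamma], delta[n_bps_gamma:]
        a = np.zeros(len(years))
        for p in preds:
            shift = float(p.dlogb_dgamma @ d_b + p.dlogs_dgamma @ d_s)
            a[yi[p.stratum.year]] += w[p.stratum.area] * p.a_hat * np.exp(shift)
        return a

    return annual_fn, np.array(years)


def qualitative_trend(index: pd.DataFrame, n_early: int = 4) -> dict:
    """Mean of the first ``n_early`` years vs the rest, and their ratio.

    Purely descriptive: the survey's real feature of interest is the early
    block (1993-1996) sitting several-fold above the later plateau.
    """
    if len(index) < 2:
        raise ValueError("need at least two years for a trend summary")
    n_early = min(n_early, len(index) - 1)
    srt = index.sort_values("year")
    col = "I_hat" if "I_hat" in srt.columns else "I_true"
    early = float(srt[col].iloc[:n_early].mean())
    late = float(srt[col].iloc[n_early:].mean())
    return {"early_years": [int(y) for y in srt["year"].iloc[:n_early]],
            "early_mean": early, "late_mean": late,
            "ratio": early / late if late > 0 else np.inf}
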