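"""The two concrete standardization models: BpS (Gamma) and SpM (Tweedie).

Biomass per sighting (BpS): Gamma GLMM with log link,

    log E[BpS_ijkl] = beta1_i + beta2_j + beta3_k
                      + b1_ij + b2_ik + b3_jk + b4_ijk + gamma * SST_ijkl

Sightings per mile (SpM): Tweedie GLMM with log link and two known offsets,

    log E[SpM_ijkt] = log(Dist_ijkt) + log(Obs_t)
                      + beta1_i + beta2_j + beta3_k + b1_ij + b2_ik + b3_jk
                      + b4_ijk + gamma' * (SST, Wind, Haze, Swell, Shadow)

with year/month/area fixed, all their 2- and 3-way interactions random, the
distance flown and the pair sighting-efficiency entering with coefficient
fixed at one, and the Tweedie power profiled.  Covariates are linear and
centred at their training means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import PairEfficiency
from .pglmm import FittedComponentModel, ModelSpec, fit, fit_tweedie_power

__all__ = [
    "RANDOM_TERMS",
    "SPM_COVARIATES",
    "bps_spec",
    "spm_spec",
    "prepare_spm_data",
    "fit_bps",
    "fit_spm",
    "screen_covariates",
]

RANDOM_TERMS: tuple[tuple[str, ...], ...] = (
    ("year", "month"), ("year", "area"), ("month", "area"),
    ("year", "month", "area"),
)
SPM_COVARIATES = ("sst", "wind", "haze", "swell", "shadow")


def bps_spec(covariates: tuple[str, ...] = ("sst",)) -> ModelSpec:
    return ModelSpec(family="gamma", response="biomass_t",
                     fixed=("year", "month", "area"),
                     covariates=tuple(covariates), random=RANDOM_TERMS)


def spm_spec(covariates: tuple[str, ...] = SPM_COVARIATES,
             var_power: float | None = None) -> ModelSpec:
    return ModelSpec(family="tweedie", response="n_sightings",
                     fixed=("year", "month", "area"),
                     covariates=tuple(covariates), random=RANDOM_TERMS,
                     offsets=("log_dist", "log_obs"), var_power=var_power)


def prepare_spm_data(cells: pd.DataFrame,
                     pair_eff: PairEfficiency | dict | None) -> pd.DataFrame:
    """Attach the two log-scale offsets to an spm_glmm-schema cell table.

    ``log_dist`` is log of the summed search distance; ``log_obs`` is log of
    the pair's relative sighting efficiency (zero when no calibration is
    supplied, i.e. all pairs treated as equal).
    """
    df = cells.copy()
    if not (df["distance_nm"] > 0).all():
        raise ValueError("all effort cells must have positive distance")
    df["log_dist"] = np.log(df["distance_nm"].to_numpy(dtype=float))
    if pair_eff is None:
        df["log_obs"] = 0.0
    else:
        eff = pair_eff.eff if isinstance(pair_eff, PairEfficiency) else dict(pair_eff)
        pairs = list(zip(df["pilot"], df["spotter"]))
        missing = sorted({p for p in pairs if p not in eff}, key=repr)
        if missing:
            raise ValueError(f"no efficiency estimate for pairs {missing}")
        vals = np.array([eff[p] for p in pairs], dtype=float)
        if np.any(vals <= 0):
            raise ValueError("pair efficiencies must be positive")
        df["log_obs"] = np.log(vals)
    return df


def fit_bps(data: pd.DataFrame, covariates: tuple[str, ...] = ("sst",),
            **engine_kw) -> FittedComponentModel:
    """Fit the Gamma biomass-per-sighting model (bps_glmm-schema input)."""
    if data["year"].nunique() < 2:
        raise ValueError("BpS model needs at least two survey years")
    return fit(bps_spec(covariates), data, **engine_kw)


def fit_spm(data: pd.DataFrame, covariates: tuple[str, ...] = SPM_COVARIATES,
            p_grid=(1.05, 1.15, 1.3, 1.5, 1.7, 1.9), refine: bool = True,
            var_power: float | None = None, **engine_kw) -> FittedComponentModel:
    """Fit the Tweedie sightings-per-mile model on prepared effort cells.

    ``data`` must carry the log_dist/log_obs offset columns (see
    :func:`prepare_spm_data`).  The Tweedie power is profiled over ``p_grid``
    unless ``var_power`` pins it.
    """
    if not (data["n_sightings"] == 0).any():
        raise ValueError("no zero-count cells: Tweedie power is not identifiable")
    if var_power is not None:
        return fit(spm_spec(covariates, var_power=var_power), data, **engine_kw)
    return fit_tweedie_power(spm_spec(covariates), data, p_grid=p_grid,
                             refine=refine, **engine_kw)


def screen_covariates(data: pd.DataFrame, component: str,
                      candidates: tuple[str, ...] = SPM_COVARIATES,
                      criterion: str = "aic", alpha: float = 0.05,
                      **fit_kw) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Backward covariate screening by Wald tests and single-drop AIC.

    Fits the full model with all candidates, then refits once per candidate
    with that covariate dropped.  Under ``criterion='aic'`` a covariate is
    retained when dropping it raises the AIC; under ``'wald'`` when its
    two-sided Wald p-value is below ``alpha``.  For the Tweedie component the
    power is profiled once on the full model and held fixed across the
    comparison refits, so AIC differences reflect the fixed effects only.
    Returns (selected covariates, decision table); the caller refits the
    final model — the input spec is never mutated.
    """
    if criterion not in ("aic", "wald"):
        raise ValueError("criterion must be 'aic' or 'wald'")

    def do_fit(covs):
        if component == "bps":
            return fit_bps(data, covariates=covs, **fit_kw)
        if component == "spm":
            return fit_spm(data, covariates=covs, **fit_kw)
        raise ValueError("component must be 'bps' or 'spm'")

    full = do_fit(tuple(candidates))
    var_power = full.var_power if component == "spm" else None
    if component == "spm":
        fit_kw = {**fit_kw, "var_power": var_power}

    from .pglmm import wald_table
    wt = wald_table(full).set_index("term")
    rows = []
    for cand in candidates:
        reduced_covs = tuple(c for c in candidates if c != cand)
        reduced = do_fit(reduced_covs)
        d_aic = reduced.aic - full.aic
        retained = d_aic > 0 if criterion == "aic" else wt.loc[cand, "p"] < alpha
        rows.append({
            "covariate": cand,
            "estimate": wt.loc[cand, "estimate"],
            "se": wt.loc[cand, "se"],
            "z": wt.loc[cand, "z"],
            "p_wald": wt.loc[cand, "p"],
            "aic_full": full.aic,
            "aic_without": reduced.aic,
            "delta_aic": d_aic,
            "retained": bool(retained),
        })
    report = pd.DataFrame(rows)
    selected = tuple(r["covariate"] for r in rows if r["retained"])
    return selected, report
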