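"""Synthetic aerial surveys with the statistical structure the analysis assumes.

The generator's defaults emulate the 1993-2009 two-spotter survey programme:
the published spotter-pair roster, the published observer size-calibration
effects and pair sighting efficiencies, the published environmental
coefficients of the two standardization models, and the published Tweedie
dispersion/power of the count model (:mod:`sbtindex.gab`).  Year effects are
engineered so the true abundance is high in 1993-1996 and roughly four times
lower afterwards, matching the shape of the real index.

Per flight-area cell the number of in-strip sightings is an integer draw
whose first two moments follow the Tweedie variance law Var = phi * mu^p
exactly (Poisson-gamma mixture with per-cell moment matching; see
docs/methods.md for why the count is not the raw compound Poisson-gamma
total).  Sighting biomasses follow the biomass-per-sighting Gamma model;
schools split each sighting by a symmetric Dirichlet; each observer's school
estimate is the true biomass times the observer's multiplicative bias times
multiplicative lognormal noise.  Every latent quantity is retained in a truth
record so parameter recovery can be verified end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gab, tweedie
from .survey_data import (AreaWeights, SchoolObservation, SightingRecord,
                          SurveyConfigError)

__all__ = ["SimConfig", "SimResult", "simulate_survey", "true_index"]

# The ~4x standardized abundance drop after 1996 is split roughly evenly
# between the two components, and a rising SST trend (with positive SST
# effects) partly masks it in the raw data — mirroring the real programme,
# where raw sighting rates stayed moderate while the standardized index fell.
_SPM_DEFAULT_YEAR_EFFECTS = {
    1993: 0.00, 1994: 0.05, 1995: -0.05, 1996: 0.02,
    1997: -0.70, 1998: -0.75, 1999: -0.80, 2000: -0.72,
    2005: -0.75, 2006: -0.85, 2007: -0.78, 2008: -0.68, 2009: -0.64,
}
_BPS_DEFAULT_YEAR_EFFECTS = {
    1993: 0.00, 1994: -0.08, 1995: 0.25, 1996: 0.40,
    1997: -0.50, 1998: -0.52, 1999: -0.62, 2000: -0.56,
    2005: -0.52, 2006: -0.45, 2007: -0.50, 2008: -0.58, 2009: -0.65,
}

RANDOM_TERMS = ("year:month", "year:area", "month:area", "year:month:area")


def _default_env():
    return {
        # the ~2 degC rise over 1993-2009 seen in the real programme; with the
        # positive SST effects it keeps raw sighting rates and mean biomasses
        # near their published annual levels while the standardized index falls
        "sst": {"mean": 20.0, "sd": 1.4, "year_trend": 0.12, "jitter": 0.3},
        "wind": {"mean": 5.0, "sd": 2.4, "lo": 0.0, "hi": 10.0, "jitter": 0.6},
        "haze": {"probs": (0.45, 0.35, 0.15, 0.05)},
        "swell": {"probs": (0.20, 0.55, 0.20, 0.05)},
        "shadow": {"probs": (0.48, 0.14, 0.10, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02)},
    }


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic survey programme."""

    years: tuple[int, ...] = tuple(sorted(gab.SPOTTER_PAIRS_BY_YEAR))
    months: tuple[int, ...] = (1, 2, 3)
    n_areas: int = 15
    area_weights: AreaWeights | None = None
    flights_per_year_month: int = 18
    areas_per_flight: int = 5
    legs_per_area: int = 2
    mean_leg_distance_nm: float = 15.0
    env: dict = field(default_factory=_default_env)
    # linear covariate effects (per unit, at log scale)
    true_coeffs: dict = field(default_factory=lambda: {
        "bps": {"sst": gab.BPS_SST_COEF},
        "spm": dict(gab.SPM_ENV_COEFS),
    })
    intercepts: dict = field(default_factory=lambda: {
        # ~88 t mean sighting; ~1.2 sightings per 100 nm for the best pair at
        # reference conditions in a high year
        "bps": float(np.log(88.0)),
        "spm": float(np.log(0.012)),
    })
    year_effects: dict = field(default_factory=lambda: {
        "bps": dict(_BPS_DEFAULT_YEAR_EFFECTS),
        "spm": dict(_SPM_DEFAULT_YEAR_EFFECTS),
    })
    month_effects: dict = field(default_factory=lambda: {
        "bps": {1: 0.0, 2: 0.10, 3: -0.05},
        "spm": {1: 0.0, 2: 0.15, 3: -0.10},
    })
    area_effect_scale: dict = field(default_factory=lambda: {"bps": 0.15, "spm": 0.45})
    re_sds: dict = field(default_factory=lambda: {
        "bps": {"year:month": 0.10, "year:area": 0.10,
                "month:area": 0.08, "year:month:area": 0.08},
        "spm": {"year:month": 0.15, "year:area": 0.20,
                "month:area": 0.10, "year:month:area": 0.10},
    })
    tweedie: dict = field(default_factory=lambda: {"p": gab.TWEEDIE_P, "phi": gab.TWEEDIE_PHI})
    gamma_shape: float = 1.1
    observer_betas: dict = field(default_factory=lambda: dict(gab.OBSERVER_SIZE_EFFECTS))
    observer_noise_cv: float = 0.25
    individual_spot_rates: dict = field(
        default_factory=gab.derive_individual_spotting_rates)
    pairs_by_year: dict = field(
        default_factory=lambda: {y: tuple(p) for y, p in gab.SPOTTER_PAIRS_BY_YEAR.items()})
    trainees: frozenset = gab.TRAINEE_OBSERVERS
    schools_geom_p: float = 0.40
    max_schools: int = 76
    school_distance_max_nm: float = 5.5
    frac_outside_strip: float = 0.03
    seed: int = 0

    def __post_init__(self):
        p, phi = self.tweedie["p"], self.tweedie["phi"]
        if not 1.0 < p < 2.0:
            raise SurveyConfigError("Tweedie p must lie in (1, 2)")
        if phi <= 0:
            raise SurveyConfigError("Tweedie phi must be positive")
        if self.gamma_shape <= 0:
            raise SurveyConfigError("gamma_shape must be positive")
        if not 0 < self.observer_noise_cv or self.observer_noise_cv > 2:
            raise SurveyConfigError("observer_noise_cv out of range")
        if self.area_weights is None:
            self.area_weights = AreaWeights.equal(range(1, self.n_areas + 1))
        missing = set(self.years) - set(self.pairs_by_year)
        if missing:
            raise SurveyConfigError(f"no spotter pairs rostered for years {sorted(missing)}")
        if self.areas_per_flight > self.n_areas:
            raise SurveyConfigError("areas_per_flight exceeds n_areas")
        for side in ("bps", "spm"):
            if any(sd < 0 for sd in self.re_sds[side].values()):
                raise SurveyConfigError("random-effect SDs must be >= 0")

    @property
    def areas(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_areas + 1))

    def pair_efficiencies(self) -> dict[tuple, float]:
        """Pair efficiency = sum of member spotting rates, best pair = 1."""
        pairs = sorted({p for y in self.years for p in self.pairs_by_year[y]})
        raw = {pr: self.individual_spot_rates[pr[0]] + self.individual_spot_rates[pr[1]]
               for pr in pairs}
        top = max(raw.values())
        return {pr: v / top for pr, v in raw.items()}

    def env_centers(self) -> dict[str, float]:
        """Population means of the covariates (the latent reference point)."""
        out = {}
        for name, spec_ in self.env.items():
            if "probs" in spec_:
                probs = np.asarray(spec_["probs"], dtype=float)
                out[name] = float(np.sum(probs * np.arange(len(probs))) / probs.sum())
            else:
                out[name] = float(spec_["mean"])
        return out

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """A smaller programme (6 years, 5 areas) for simulation studies."""
        base = dict(
            years=(1993, 1994, 1995, 1996, 1997, 1998),
            n_areas=5,
            flights_per_year_month=14,
            areas_per_flight=3,
            mean_leg_distance_nm=20.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimResult:
    """Simulated survey: effort legs, sightings, and the latent truth record."""

    legs: pd.DataFrame
    sightings: list[SightingRecord]
    truth: dict


def _area_effects(cfg: SimConfig, side: str) -> dict[int, float]:
    # deterministic, config-derived spatial pattern: inshore/shelf-break
    # richer than mid-shore, mirroring where real sightings concentrate
    scale = cfg.area_effect_scale[side]
    areas = cfg.areas
    k = len(areas)
    vals = scale * np.cos(2.0 * np.pi * np.arange(k) / max(k - 1, 1))
    vals -= vals[0]  # first area is the reference level
    return {a: float(v) for a, v in zip(areas, vals)}


def _draw_random_effects(cfg: SimConfig, rng: np.random.Generator, side: str) -> dict:
    sds = cfg.re_sds[side]
    crossings = {
        "year:month": list(itertools.product(cfg.years, cfg.months)),
        "year:area": list(itertools.product(cfg.years, cfg.areas)),
        "month:area": list(itertools.product(cfg.months, cfg.areas)),
        "year:month:area": list(itertools.product(cfg.years, cfg.months, cfg.areas)),
    }
    return {term: {combo: float(rng.normal(0.0, sds[term])) for combo in combos}
            for term, combos in crossings.items()}


def _stratum_linpred(cfg: SimConfig, truth_side: dict, year: int, month: int,
                     area: int) -> float:
    """Latent linear predictor for a stratum at reference covariates."""
    re = truth_side["random_effects"]
    return (truth_side["intercept"]
            + truth_side["year_effects"][year]
            + truth_side["month_effects"][month]
            + truth_side["area_effects"][area]
            + re["year:month"][(year, month)]
            + re["year:area"][(year, area)]
            + re["month:area"][(month, area)]
            + re["year:month:area"][(year, month, area)])


def simulate_survey(cfg: SimConfig,
                    rng: np.random.Generator | None = None) -> SimResult:
    """Generate one synthetic survey programme.

    Returns effort legs (one row per searched leg with environmental
    readings), the sighting records with per-school per-observer biomass
    estimates and perpendicular distances, and a truth record holding every
    latent parameter plus the noise-free standardized annual index.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    centers = cfg.env_centers()
    pair_eff = cfg.pair_efficiencies()
    truth = {
        "env_centers": centers,
        "pair_efficiencies": pair_eff,
        "observer_betas": dict(cfg.observer_betas),
        "individual_spot_rates": dict(cfg.individual_spot_rates),
    }
    for side in ("bps", "spm"):
        truth[side] = {
            "intercept": cfg.intercepts[side],
            "coeffs": dict(cfg.true_coeffs[side]),
            "year_effects": {y: cfg.year_effects[side].get(y, 0.0) for y in cfg.years},
            "month_effects": {m: cfg.month_effects[side].get(m, 0.0) for m in cfg.months},
            "area_effects": _area_effects(cfg, side),
            "random_effects": _draw_random_effects(cfg, rng, side),
        }

    p_tw, phi_tw = cfg.tweedie["p"], cfg.tweedie["phi"]
    sigma_ln = float(np.sqrt(np.log1p(cfg.observer_noise_cv ** 2)))
    betas = cfg.observer_betas

    leg_rows = []
    sightings: list[SightingRecord] = []
    sighting_counter = 0
    year0 = cfg.years[0]

    for year in cfg.years:
        roster = cfg.pairs_by_year[year]
        for month in cfg.months:
            for f in range(cfg.flights_per_year_month):
                day = f + 1
                pair = roster[rng.integers(len(roster))]
                pilot, spotter = pair
                plane = f"P{roster.index(pair) + 1}"
                fkey = (year, month, day, plane)
                e_pilot = cfg.individual_spot_rates.get(pilot, 1.0)
                e_spot = cfg.individual_spot_rates.get(spotter, 1.0)
                p_made_by_spotter = e_spot / (e_pilot + e_spot)

                # flight-level environment
                sst_f = rng.normal(
                    cfg.env["sst"]["mean"]
                    + cfg.env["sst"].get("year_trend", 0.0) * (year - year0),
                    cfg.env["sst"]["sd"])
                wind_f = float(np.clip(rng.normal(cfg.env["wind"]["mean"],
                                                  cfg.env["wind"]["sd"]),
                                       cfg.env["wind"]["lo"], cfg.env["wind"]["hi"]))
                discrete = {name: int(rng.choice(len(cfg.env[name]["probs"]),
                                                 p=cfg.env[name]["probs"]))
                            for name in ("haze", "swell", "shadow")}

                flight_areas = rng.choice(cfg.areas, size=cfg.areas_per_flight,
                                          replace=False)
                for area in sorted(int(a) for a in flight_areas):
                    sst = float(np.clip(sst_f + rng.normal(0.0, cfg.env["sst"]["jitter"]),
                                        5.5, 34.5))
                    wind = float(np.clip(wind_f + rng.normal(0.0, cfg.env["wind"]["jitter"]),
                                         0.0, None))
                    env = {"sst": sst, "wind": wind, **discrete}
                    dists = rng.gamma(4.0, cfg.mean_leg_distance_nm / 4.0,
                                      size=cfg.legs_per_area)
                    dists = np.clip(dists, 1.0, None)
                    for d in dists:
                        leg_rows.append({"year": year, "month": month, "day": day,
                                         "plane": plane, "area": area,
                                         "pilot": pilot, "spotter": spotter,
                                         "distance_nm": float(d), **env})
                    dist_cell = float(dists.sum())

                    eta = (_stratum_linpred(cfg, truth["spm"], year, month, area)
                           + sum(cfg.true_coeffs["spm"][e] * (env[e] - centers[e])
                                 for e in cfg.true_coeffs["spm"]))
                    mu_cell = dist_cell * pair_eff[pair] * float(np.exp(eta))
                    n_sight = int(tweedie.sample_count_matched_moments(
                        rng, np.array([mu_cell]), phi_tw, p_tw)[0])

                    eta_b = (_stratum_linpred(cfg, truth["bps"], year, month, area)
                             + sum(cfg.true_coeffs["bps"][e] * (env[e] - centers[e])
                                   for e in cfg.true_coeffs["bps"]))
                    mean_bps = float(np.exp(eta_b))

                    n_extra = rng.poisson(cfg.frac_outside_strip * mu_cell)
                    for j in range(n_sight + n_extra):
                        outside = j >= n_sight
                        sighting_counter += 1
                        sid = f"S{sighting_counter:06d}"
                        made_by = spotter if rng.random() < p_made_by_spotter else pilot
                        total = rng.gamma(cfg.gamma_shape, mean_bps / cfg.gamma_shape)
                        total = max(total, 0.05)
                        k = min(int(rng.geometric(cfg.schools_geom_p)), cfg.max_schools)
                        shares = rng.dirichlet(np.ones(k))
                        if outside:
                            center = rng.uniform(6.3, 7.5)
                        else:
                            center = rng.uniform(0.0, cfg.school_distance_max_nm)
                        schools = []
                        for si, share in enumerate(shares):
                            true_school = max(total * share, 0.01)
                            dist_s = float(np.clip(center + rng.uniform(-0.5, 0.5),
                                                   6.01 if outside else 0.0, None))
                            ests = {}
                            for obs in pair:
                                if obs in cfg.trainees and obs != pilot:
                                    continue
                                noise = float(np.exp(rng.normal(-0.5 * sigma_ln ** 2,
                                                                sigma_ln)))
                                ests[obs] = true_school * betas.get(obs, 1.0) * noise
                            if not ests:  # both members trainees: keep pilot's view
                                ests[pilot] = true_school * betas.get(pilot, 1.0)
                            schools.append(SchoolObservation(
                                school_id=f"{sid}-{si + 1}", sighting_id=sid,
                                raw_estimates=ests, distance_nm=dist_s))
                        sightings.append(SightingRecord(
                            sighting_id=sid, flight_key=fkey, area=area,
                            schools=schools, made_by=made_by))

    legs = pd.DataFrame(leg_rows)
    truth["true_index"] = true_index(cfg, truth)
    return SimResult(legs=legs, sightings=sightings, truth=truth)


def true_index(cfg: SimConfig, truth: dict,
               ref_env: dict[str, float] | None = None) -> pd.DataFrame:
    """Noise-free standardized annual index implied by the latent parameters.

    Evaluates both component models at the reference covariates (``ref_env``,
    default the configured population centres), best pair (Obs = 1) and
    100 nm of effort, combines strata multiplicatively, area-weights, sums
    within year and normalises to mean one.  Columns: year, A_true, I_true.
    """
    centers = truth["env_centers"]
    ref_env = dict(centers if ref_env is None else ref_env)
    rows = []
    for year in cfg.years:
        a_year = 0.0
        for month in cfg.months:
            for area in cfg.areas:
                eta_s = (_stratum_linpred(cfg, truth["spm"], year, month, area)
                         + sum(truth["spm"]["coeffs"][e] * (ref_env[e] - centers[e])
                               for e in truth["spm"]["coeffs"]))
                s_hat = 100.0 * np.exp(eta_s)  # per 100 nm, Obs = 1
                eta_b = (_stratum_linpred(cfg, truth["bps"], year, month, area)
                         + sum(truth["bps"]["coeffs"][e] * (ref_env[e] - centers[e])
                               for e in truth["bps"]["coeffs"]))
                a_year += cfg.area_weights[area] * s_hat * np.exp(eta_b)
        rows.append({"year": year, "A_true": a_year})
    out = pd.DataFrame(rows)
    out["I_true"] = out["A_true"] / out["A_true"].mean()
    return out
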