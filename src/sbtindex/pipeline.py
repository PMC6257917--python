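"""End-to-end orchestration: data in, standardized index with CVs out.

Stages (each logged with record counts so the data flow is auditable):

1. load the four survey tables from CSV, or simulate them;
2. strip-filter sightings to the configured half-width;
3. school-size inter-calibration, adjustment, biomass per sighting;
4. effort aggregation to flight-area cells and pair-efficiency calibration;
5. component model fits (Gamma BpS, Tweedie SpM; optional covariate screen);
6. standardized predictions, annual index, variance decomposition, CIs;
7. artifacts: CSV tables, JSON model bundles, a run manifest with the
   config hash so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, pglmm, standardize
from .index import (ReferenceConditions, annual_index, qualitative_trend,
                    standardized_predictions)
from .simulate import SimConfig, SimResult, simulate_survey
from .survey_data import (SCHEMAS, AreaWeights, SightingRecord, SurveyConfig,
                          SurveyConfigError, SchoolObservation, SurveyStratum,
                          aggregate_effort, effort_cells_to_frame,
                          read_dataset, strip_filter, write_dataset)
from .uncertainty import index_with_uncertainty

__all__ = ["RunConfig", "PipelineResult", "run",
           "sightings_to_school_frame", "observer_counts", "build_bps_table"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None  # schema name -> CSV path
    survey: SurveyConfig = field(default_factory=SurveyConfig)
    reference_observer: object = None     # default: observer with most estimates
    screen: bool = False
    p_grid: tuple[float, ...] = (1.05, 1.15, 1.3, 1.5, 1.7, 1.9)
    refine_p: bool = True
    var_power: float | None = None        # pin the Tweedie power instead of profiling
    bps_covariates: tuple[str, ...] = ("sst",)
    spm_covariates: tuple[str, ...] = standardize.SPM_COVARIATES
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.simulate is None and not self.inputs:
            raise SurveyConfigError("config needs either a simulate block or input paths")
        if self.inputs:
            unknown = set(self.inputs) - set(SCHEMAS)
            if unknown:
                raise SurveyConfigError(f"unknown input schemas {sorted(unknown)}")
        if self.simulate is not None:
            # keep stratification consistent between generator and readers
            self.survey = dataclasses.replace(
                self.survey, years=tuple(self.simulate.years),
                months=tuple(self.simulate.months),
                n_areas=self.simulate.n_areas,
                area_weights=self.simulate.area_weights)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SurveyConfigError(f"unknown config keys: {sorted(unknown)}")
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("years", "months"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "area_weights" in sim and sim["area_weights"] is not None:
                sim["area_weights"] = AreaWeights(
                    {int(k): float(v) for k, v in sim["area_weights"].items()})
            raw["simulate"] = SimConfig(**sim)
        for key in ("p_grid", "bps_covariates", "spm_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    size_calibration: calibration.SizeCalibration
    pair_efficiency: calibration.PairEfficiency | None
    bps_model: pglmm.FittedComponentModel
    spm_model: pglmm.FittedComponentModel
    reference: ReferenceConditions
    predictions: list
    index: pd.DataFrame
    variance: object
    trend: dict
    screening: dict[str, pd.DataFrame] | None
    truth: dict | None
    manifest: dict


# ---------------------------------------------------------------------------
# table builders shared by the pipeline, the CLI and the simulator writers
# ---------------------------------------------------------------------------

def sightings_to_school_frame(sightings: list[SightingRecord]) -> pd.DataFrame:
    """bps_observer-schema frame: one row per (school, observer) estimate."""
    rows = []
    for s in sightings:
        for sch in s.schools:
            for obs, est in sch.raw_estimates.items():
                rows.append({"sighting_id": s.sighting_id, "school_id": sch.school_id,
                             "observer": obs, "biomass_t": est,
                             "distance_nm": sch.distance_nm})
    return pd.DataFrame(rows, columns=list(SCHEMAS["bps_observer"]))


def observer_counts(legs: pd.DataFrame,
                    sightings: list[SightingRecord]) -> pd.DataFrame:
    """spm_observer-schema frame: per-flight per-observer sighting counts.

    Every flight present in the effort legs contributes a row for each of its
    two spotters, zero counts included.
    """
    made = {}
    for s in sightings:
        made[(s.flight_key, s.made_by)] = made.get((s.flight_key, s.made_by), 0) + 1
    rows = []
    flights = legs[["year", "month", "day", "plane", "pilot", "spotter"]].drop_duplicates()
    for _, f in flights.iterrows():
        fkey = (int(f["year"]), int(f["month"]), int(f["day"]), f["plane"])
        for obs in (f["pilot"], f["spotter"]):
            rows.append({"year": fkey[0], "month": fkey[1], "day": fkey[2],
                         "plane": fkey[3], "pilot": f["pilot"], "spotter": f["spotter"],
                         "observer": obs, "n_sightings": made.get((fkey, obs), 0)})
    return pd.DataFrame(rows, columns=list(SCHEMAS["spm_observer"]))


def build_bps_table(sightings: list[SightingRecord], bps_response: pd.DataFrame,
                    cells_frame: pd.DataFrame) -> pd.DataFrame:
    """bps_glmm-schema frame: per-sighting adjusted biomass with stratum + SST.

    SST for a sighting is the averaged reading of its flight-area effort cell
    (SST is matched as given in the data; no interpolation here).
    """
    env_lookup = {(int(r["year"]), int(r["month"]), int(r["day"]), r["plane"],
                   int(r["area"])): float(r["sst"])
                  for _, r in cells_frame.iterrows()}
    resp = dict(zip(bps_response["sighting_id"], bps_response["biomass_t"]))
    rows = []
    for s in sightings:
        key = (*s.flight_key, s.area)
        if key not in env_lookup:
            raise ValueError(f"sighting {s.sighting_id}: no effort cell for {key}")
        if s.sighting_id not in resp:
            continue  # e.g. biomass could not be adjusted
        rows.append({"sighting_id": s.sighting_id, "year": s.flight_key[0],
                     "month": s.flight_key[1], "area": s.area,
                     "sst": env_lookup[key], "biomass_t": resp[s.sighting_id]})
    return pd.DataFrame(rows, columns=list(SCHEMAS["bps_glmm"]))


def _sightings_from_frames(schools: pd.DataFrame,
                           meta: pd.DataFrame) -> list[SightingRecord]:
    """Reassemble SightingRecords from a school table + per-sighting metadata."""
    meta_idx = meta.set_index("sighting_id")
    out = []
    for sid, grp in schools.groupby("sighting_id", sort=True):
        m = meta_idx.loc[sid]
        sch = []
        for school_id, sgrp in grp.groupby("school_id", sort=True):
            ests = dict(zip(sgrp["observer"], sgrp["biomass_t"]))
            sch.append(SchoolObservation(school_id=school_id, sighting_id=sid,
                                         raw_estimates=ests,
                                         distance_nm=float(sgrp["distance_nm"].iloc[0])))
        out.append(SightingRecord(
            sighting_id=sid,
            flight_key=(int(m["year"]), int(m["month"]), int(m["day"]), m["plane"]),
            area=int(m["area"]), schools=sch,
            made_by=m.get("made_by")))
    return out


def _json_default(o):
    if hasattr(o, "item"):
        return o.item()
    if isinstance(o, (set, frozenset, tuple)):
        return list(o)
    return str(o)


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> PipelineResult:
    """Execute the full standardization analysis for one configuration."""
    rng = np.random.default_rng(config.seed)
    truth = None
    legs = None
    sightings: list[SightingRecord] = []

    if config.simulate is not None:
        log.info("stage simulate: generating synthetic survey (seed %d)", config.seed)
        sim = simulate_survey(config.simulate, rng=rng)
        legs, sightings = sim.legs, sim.sightings
        truth = sim.truth
        log.info("  %d effort legs, %d raw sightings", len(legs), len(sightings))

        half = config.survey.strip_half_width_nm
        kept = strip_filter(sightings, half)
        log.info("stage strip_filter: %d of %d sightings within +/-%g nm",
                 len(kept), len(sightings), half)

        schools = sightings_to_school_frame(kept)
        ref_obs = config.reference_observer
        if ref_obs is None:
            ref_obs = schools["observer"].value_counts().idxmax()
        calib = calibration.fit_size_calibration(schools, reference=ref_obs)
        calib = calib.with_unit_defaults(pd.unique(schools["observer"]))
        adjusted = calibration.adjust_school_sizes(schools, calib)
        bps_resp = calibration.sighting_biomass(adjusted)
        log.info("stage size_calibration: %d observers, reference %r, "
                 "%d sighting biomasses", len(calib.beta), ref_obs, len(bps_resp))

        cells = aggregate_effort(legs, kept)
        cells_frame = effort_cells_to_frame(cells)
        counts = observer_counts(legs, kept)
        pair_eff = calibration.fit_pair_efficiency(counts)
        log.info("stage effort: %d flight-area cells (%d with zero sightings); "
                 "%d observer pairs calibrated",
                 len(cells), int((cells_frame["n_sightings"] == 0).sum()),
                 len(pair_eff.eff))

        bps_data = build_bps_table(kept, bps_resp, cells_frame)
    else:
        # CSV mode mirrors the survey's released tables: the GLMM inputs are
        # model-ready (strip-filtered, biomass already observer-adjusted), and
        # the two observer tables drive the calibrations
        log.info("stage load: reading survey CSVs")
        needed = {"bps_observer", "bps_glmm", "spm_observer", "spm_glmm"}
        missing = needed - set(config.inputs or {})
        if missing:
            raise SurveyConfigError(f"CSV mode needs all four tables; missing {sorted(missing)}")
        schools = read_dataset(config.inputs["bps_observer"], "bps_observer",
                               config.survey)
        bps_data = read_dataset(config.inputs["bps_glmm"], "bps_glmm", config.survey)
        counts = read_dataset(config.inputs["spm_observer"], "spm_observer",
                              config.survey)
        cells_frame = read_dataset(config.inputs["spm_glmm"], "spm_glmm", config.survey)
        kept = []
        ref_obs = config.reference_observer
        if ref_obs is None:
            ref_obs = schools["observer"].value_counts().idxmax()
        calib = calibration.fit_size_calibration(schools, reference=ref_obs)
        pair_eff = calibration.fit_pair_efficiency(counts)
        log.info("  %d sightings, %d effort cells, %d observers, %d pairs",
                 len(bps_data), len(cells_frame), len(calib.beta), len(pair_eff.eff))

    spm_data = standardize.prepare_spm_data(cells_frame, pair_eff)

    screening = None
    bps_covs, spm_covs = tuple(config.bps_covariates), tuple(config.spm_covariates)
    if config.screen:
        log.info("stage screen: backward covariate screening")
        bps_covs, bps_rep = standardize.screen_covariates(
            bps_data, "bps", candidates=tuple(standardize.SPM_COVARIATES))
        spm_covs, spm_rep = standardize.screen_covariates(
            spm_data, "spm", candidates=tuple(standardize.SPM_COVARIATES),
            p_grid=config.p_grid, refine=False)
        screening = {"bps": bps_rep, "spm": spm_rep}
        log.info("  retained: BpS %s, SpM %s", bps_covs, spm_covs)

    bps_covs_present = tuple(c for c in bps_covs if c in bps_data.columns)
    bps_model = standardize.fit_bps(bps_data, covariates=bps_covs_present)
    log.info("stage fit_bps: n=%d, deviance explained %.1f%%",
             bps_model.n, 100 * bps_model.deviance_explained)
    spm_model = standardize.fit_spm(spm_data, covariates=spm_covs,
                                    p_grid=config.p_grid, refine=config.refine_p,
                                    var_power=config.var_power)
    log.info("stage fit_spm: n=%d, p=%.3f, phi=%.3f, deviance explained %.1f%%",
             spm_model.n, spm_model.var_power, spm_model.phi,
             100 * spm_model.deviance_explained)

    ref = ReferenceConditions.from_effort(cells_frame)
    strata = [SurveyStratum(y, m, a)
              for y in sorted(cells_frame["year"].unique())
              for m in sorted(cells_frame["month"].unique())
              for a in sorted(cells_frame["area"].unique())]
    preds, cond_cov = standardized_predictions(bps_model, spm_model, ref, strata,
                                               with_cov=True)
    index, decomp = index_with_uncertainty(preds, config.survey.area_weights,
                                           bps_model, spm_model,
                                           cond_cov=cond_cov)
    trend = qualitative_trend(index)
    log.info("stage index: %d years, mean CV %.2f, early/late ratio %.2f",
             len(index), float(index["cv"].mean()), trend["ratio"])

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sightings_raw": len(sightings) if sightings else len(bps_data),
        "n_sightings_in_strip": len(kept) if kept else len(bps_data),
        "n_effort_cells": len(cells_frame),
        "reference_env": ref.env,
        "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    result = PipelineResult(
        size_calibration=calib, pair_efficiency=pair_eff, bps_model=bps_model,
        spm_model=spm_model, reference=ref, predictions=preds, index=index,
        variance=decomp, trend=trend, screening=screening, truth=truth,
        manifest=manifest)

    if config.outdir:
        _write_artifacts(config, result, legs, kept, cells_frame, bps_data)
    return result


def _write_artifacts(config: RunConfig, res: PipelineResult, legs, sightings,
                     cells_frame, bps_data) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if legs is not None and sightings:
        write_dataset(sightings_to_school_frame(sightings), out / "bps_observer.csv",
                      "bps_observer")
        write_dataset(observer_counts(legs, sightings), out / "spm_observer.csv",
                      "spm_observer")
    write_dataset(bps_data, out / "bps_glmm.csv", "bps_glmm")
    write_dataset(cells_frame, out / "spm_glmm.csv", "spm_glmm")
    res.size_calibration.to_frame().to_csv(out / "size_calibration.csv", index=False)
    if res.pair_efficiency is not None:
        res.pair_efficiency.to_frame().to_csv(out / "pair_efficiency.csv", index=False)
    res.index.to_csv(out / "index_series.csv", index=False)
    res.variance.to_frame().to_csv(out / "variance_decomposition.csv", index=False)
    if res.screening:
        for side, rep in res.screening.items():
            rep.to_csv(out / f"screening_{side}.csv", index=False)
    for side, model in (("bps", res.bps_model), ("spm", res.spm_model)):
        with open(out / f"model_{side}.json", "w") as fh:
            json.dump(pglmm.to_bundle(model), fh, default=_json_default)
    if res.truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump({"true_index": res.truth["true_index"].to_dict(orient="list"),
                       "env_centers": res.truth["env_centers"],
                       "pair_efficiencies": {repr(k): v for k, v in
                                             res.truth["pair_efficiencies"].items()},
                       "observer_betas": res.truth["observer_betas"]},
                      fh, default=_json_default)
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=_json_default)
    log.info("artifacts written to %s", out)
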