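"""Observer calibration: school-size biases and pair sighting efficiencies.

Two calibrations precede the standardization models:

* **School-size inter-calibration.**  Each school gets independent biomass
  estimates from the two spotters aboard.  Under a multiplicative error
  model, the log-ratio of two observers' estimates of the same school has
  mean ``log beta_A - log beta_B``; regressing the per-school log-ratios on a
  signed observer-incidence design (least squares, reference observer's
  column dropped so ``beta_ref == 1``) recovers every observer's
  multiplicative effect as long as the observer-overlap graph is connected.
  Raw estimates are then divided by the estimating observer's beta, bringing
  all observers onto the reference scale; ``beta = 0.81`` means that observer
  underestimates sizes by 19%.

* **Pair sighting efficiency.**  Within a flight both spotters face the same
  abundance and conditions, so the split of sightings between them reflects
  their relative spotting skill only.  Conditioning on each flight's total
  makes the per-observer counts binomial with log-odds equal to the
  difference of the members' log-efficiencies — a binomial GLM on signed
  incidence rows, with the flight nuisance effects cancelled exactly.  A
  pair's efficiency is the sum of its members' rates, scaled so the best pair
  is exactly one; it enters the count model as a known offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationError",
    "SizeCalibration",
    "PairEfficiency",
    "fit_size_calibration",
    "adjust_school_sizes",
    "sighting_biomass",
    "fit_pair_efficiency",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Calibration not identifiable (disconnected observer graph) or misused."""


@dataclass
class SizeCalibration:
    """Multiplicative school-size effect per observer, relative to a reference."""

    reference_observer: object
    beta: dict[object, float]
    se: dict[object, float | None]

    def __post_init__(self):
        if self.beta.get(self.reference_observer) != 1.0:
            raise CalibrationError("reference observer must have beta == 1")
        if any(b <= 0 for b in self.beta.values()):
            raise CalibrationError("all beta must be positive")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"observer": o, "beta": b,
                 "se": self.se.get(o) if o != self.reference_observer else np.nan}
                for o, b in sorted(self.beta.items(), key=lambda kv: str(kv[0]))]
        return pd.DataFrame(rows)

    def with_unit_defaults(self, observers) -> "SizeCalibration":
        """Extend with beta = 1 for observers that could not be calibrated.

        An observer who never co-estimates a school with anyone (e.g. a pilot
        always flying with trainees who made no estimates) is unreachable in
        the overlap graph; their estimates are used unadjusted, matching how
        such observers are simply absent from a published calibration table.
        """
        beta = dict(self.beta)
        se = dict(self.se)
        added = [o for o in observers if o not in beta]
        for o in added:
            beta[o] = 1.0
            se[o] = None
        if added:
            log.warning("size calibration: %d uncalibratable observers kept at "
                        "beta = 1: %s", len(added), sorted(added, key=str))
        return SizeCalibration(reference_observer=self.reference_observer,
                               beta=beta, se=se)


@dataclass
class PairEfficiency:
    """Relative sighting power per (pilot, spotter) pair; the best pair is 1."""

    eff: dict[tuple, float]
    individual: dict[object, float]

    def __post_init__(self):
        vals = list(self.eff.values())
        if not vals or abs(max(vals) - 1.0) > 1e-12:
            raise CalibrationError("maximum pair efficiency must equal 1 exactly")
        if any(not 0 < v <= 1 for v in vals):
            raise CalibrationError("pair efficiencies must lie in (0, 1]")

    @property
    def reference_pair(self) -> tuple:
        return max(self.eff, key=self.eff.get)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pilot": p, "spotter": s, "efficiency": v}
                for (p, s), v in sorted(self.eff.items(), key=lambda kv: str(kv[0]))]
        return pd.DataFrame(rows)


def _connected_component(edges: list[tuple], start) -> set:
    adj: dict[object, set] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen, stack = {start}, [start]
    while stack:
        for nb in adj.get(stack.pop(), ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def fit_size_calibration(schools: pd.DataFrame, reference) -> SizeCalibration:
    """Least-squares inter-calibration of school-size estimates.

    ``schools`` is bps_observer-schema: one row per (school, observer)
    estimate.  Per-school log-ratios of paired estimates are regressed on a
    signed incidence design; the reference observer's column is dropped, so
    ``beta_obs = exp(coef_obs)`` is the ratio of that observer's expected
    estimate to the reference observer's.  SEs for beta follow by the delta
    method from the Gaussian fit.
    """
    required = {"school_id", "observer", "biomass_t"}
    if missing := required - set(schools.columns):
        raise CalibrationError(f"schools table lacks columns {sorted(missing)}")

    observers = sorted(pd.unique(schools["observer"]), key=str)
    if reference not in observers:
        raise CalibrationError(f"reference observer {reference!r} has no estimates")

    rows, resp, edges = [], [], []
    n_skipped = 0
    for _, grp in schools.groupby("school_id", sort=True):
        obs = list(grp["observer"])
        est = dict(zip(grp["observer"], grp["biomass_t"]))
        if len(obs) < 2:
            n_skipped += 1
            continue
        obs_sorted = sorted(obs, key=str)
        for i in range(len(obs_sorted)):
            for j in range(i + 1, len(obs_sorted)):
                a, b = obs_sorted[i], obs_sorted[j]
                rows.append((a, b))
                resp.append(np.log(est[a]) - np.log(est[b]))
                edges.append((a, b))
    if n_skipped:
        log.info("size calibration: %d schools with <2 estimates skipped", n_skipped)
    if not rows:
        raise CalibrationError("no schools with paired estimates")

    reachable = _connected_component(edges, reference)
    paired_obs = {o for e in edges for o in e}
    unreachable = sorted(paired_obs - reachable, key=str)
    if unreachable:
        raise CalibrationError(
            f"observer-overlap graph is disconnected; unreachable from reference "
            f"{reference!r}: {unreachable}")

    free = [o for o in sorted(paired_obs, key=str) if o != reference]
    col = {o: i for i, o in enumerate(free)}
    X = np.zeros((len(rows), len(free)))
    for r, (a, b) in enumerate(rows):
        if a != reference:
            X[r, col[a]] += 1.0
        if b != reference:
            X[r, col[b]] -= 1.0
    y = np.asarray(resp)

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(rows) - len(free), 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se_log = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))

    beta = {reference: 1.0}
    se = {reference: None}
    for o in free:
        b = float(np.exp(coef[col[o]]))
        beta[o] = b
        se[o] = float(b * se_log[col[o]])  # delta method on exp scale
    return SizeCalibration(reference_observer=reference, beta=beta, se=se)


def adjust_school_sizes(schools: pd.DataFrame,
                        calib: SizeCalibration) -> pd.DataFrame:
    """Bring raw estimates onto the reference scale and average per school.

    Each raw estimate is divided by its observer's beta; a school's final
    biomass is the mean of its adjusted estimates (a single estimate — e.g.
    from a flight with a trainee — stands alone).  Adjusted biomasses are
    treated as exact downstream.  Returns one row per school with columns
    school_id, sighting_id, biomass_t and, when present, distance_nm.
    """
    unknown = sorted(set(schools["observer"]) - set(calib.beta), key=str)
    if unknown:
        raise CalibrationError(f"observers without calibration: {unknown}")
    df = schools.copy()
    df["adjusted"] = df["biomass_t"] / df["observer"].map(calib.beta)
    keys = ["school_id"]
    carried = [c for c in ("sighting_id", "distance_nm") if c in df.columns]
    agg = {"adjusted": "mean", **{c: "first" for c in carried}}
    out = df.groupby(keys, sort=True, as_index=False).agg(agg)
    return out.rename(columns={"adjusted": "biomass_t"})[keys + ["biomass_t"] + carried]


def sighting_biomass(adjusted_schools: pd.DataFrame) -> pd.DataFrame:
    """Total adjusted biomass per sighting (the BpS response)."""
    if "sighting_id" not in adjusted_schools.columns:
        raise CalibrationError("adjusted schools table lacks sighting_id")
    if adjusted_schools.empty:
        raise CalibrationError("no schools to aggregate")
    out = (adjusted_schools.groupby("sighting_id", sort=True, as_index=False)
           ["biomass_t"].sum())
    if not (out["biomass_t"] > 0).all():
        raise CalibrationError("non-positive sighting biomass after adjustment")
    return out


def fit_pair_efficiency(counts: pd.DataFrame) -> PairEfficiency:
    """Relative sighting efficiency of observer pairs from within-flight splits.

    ``counts`` is spm_observer-schema: one row per (flight, observer) with
    that observer's sighting count.  Within each two-observer flight the
    counts are conditioned on the flight total (a binomial split), which
    cancels the flight's abundance/conditions nuisance effect; the binomial
    GLM on signed incidence rows estimates each observer's log spotting rate
    relative to a baseline.  Pair efficiency = sum of the members' rates,
    normalised so the best pair is exactly 1.
    """
    required = {"year", "month", "day", "plane", "pilot", "spotter",
                "observer", "n_sightings"}
    if missing := required - set(counts.columns):
        raise CalibrationError(f"counts table lacks columns {sorted(missing)}")

    flight_cols = ["year", "month", "day", "plane"]
    rows, edges = [], []
    pairs = set()
    for _, grp in counts.groupby(flight_cols, sort=True):
        pilot = grp["pilot"].iloc[0]
        spotter = grp["spotter"].iloc[0]
        pairs.add((pilot, spotter))
        by_obs = grp.groupby("observer")["n_sightings"].sum()
        if len(by_obs) != 2:
            continue  # efficiency is only identified from two-spotter flights
        (a, n_a), (b, n_b) = sorted(by_obs.items(), key=lambda kv: str(kv[0]))
        if n_a + n_b == 0:
            continue
        rows.append((a, b, int(n_a), int(n_b)))
        edges.append((a, b))
    if not rows:
        raise CalibrationError("no two-observer flights with sightings")

    observers = sorted({o for e in edges for o in e}, key=str)
    baseline = observers[0]
    reachable = _connected_component(edges, baseline)
    unreachable = sorted(set(observers) - reachable, key=str)
    if unreachable:
        raise CalibrationError(
            f"observer graph is disconnected; components split at: {unreachable}")

    free = [o for o in observers if o != baseline]
    col = {o: i for i, o in enumerate(free)}
    X = np.zeros((len(rows), len(free) + 1))
    X[:, 0] = 0.0  # no intercept: flight effects cancel in the conditional split
    endog = np.zeros((len(rows), 2))
    for r, (a, b, n_a, n_b) in enumerate(rows):
        if a != baseline:
            X[r, 1 + col[a]] += 1.0
        if b != baseline:
            X[r, 1 + col[b]] -= 1.0
        endog[r] = (n_a, n_b)
    X = X[:, 1:]  # drop the placeholder column

    if X.shape[1] == 0:  # single distinct observer pairing, symmetric case
        logrates = {baseline: 0.0}
    else:
        glm = sm.GLM(endog, X, family=sm.families.Binomial())
        res = glm.fit()
        logrates = {baseline: 0.0}
        for o in free:
            logrates[o] = float(res.params[col[o]])

    # observers never seen in a usable split (e.g. only solo flights) are
    # unidentifiable; pairs involving them are excluded up front by the
    # connectivity check, so every rostered pair member has a rate here
    missing = sorted({o for p in pairs for o in p} - set(logrates), key=str)
    if missing:
        raise CalibrationError(
            f"observers with no identifiable within-flight splits: {missing}")

    rates = {o: float(np.exp(v)) for o, v in logrates.items()}
    raw = {p: rates[p[0]] + rates[p[1]] for p in pairs}
    top = max(raw.values())
    eff = {p: v / top for p, v in raw.items()}
    best = max(eff, key=eff.get)
    eff[best] = 1.0  # exact, despite floating division
    return PairEfficiency(eff=eff, individual=rates)
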