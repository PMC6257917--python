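"""Domain types, CSV schemas and strip-transect plumbing for the aerial survey.

The survey design: planes fly fixed north-south transect lines over the Great
Australian Bight each January-March, two spotters per plane searching for
surface schools of juvenile southern bluefin tuna.  A *sighting* is the
spotter-defined detection event and may comprise many *schools*; each school
receives an independent biomass estimate (tonnes) from each spotter.  Search
effort and sightings are analysed on a strip of fixed half-width around the
transect line, stratified into areas.

Four CSV schemas mirror the shapes the downstream models consume:

``bps_observer``
    one row per (school, observer) biomass estimate — input to the
    school-size inter-calibration.
``bps_glmm``
    one row per sighting with adjusted total biomass and SST — input to the
    biomass-per-sighting model.
``spm_observer``
    one row per (flight, observer) sighting count — input to the pair
    sighting-efficiency calibration.
``spm_glmm``
    one row per flight-area effort cell — input to the sightings-per-mile
    model.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurveyConfigError",
    "SchemaError",
    "ValidationError",
    "SurveyStratum",
    "SchoolObservation",
    "SightingRecord",
    "EffortCell",
    "AreaWeights",
    "SurveyConfig",
    "SCHEMAS",
    "MONTH_NAMES",
    "read_dataset",
    "write_dataset",
    "strip_filter",
    "aggregate_effort",
    "sightings_rate_per_100nm",
]


class SurveyConfigError(ValueError):
    """Invalid survey configuration."""


class SchemaError(ValueError):
    """CSV does not match the requested dataset schema."""


class ValidationError(ValueError):
    """Rows violate range/consistency rules; offending row numbers attached."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


#: survey window months; the survey flies January through March only
MONTH_NAMES = {1: "Jan", 2: "Feb", 3: "Mar"}
_MONTH_LOOKUP = {v.lower(): k for k, v in MONTH_NAMES.items()}
_MONTH_LOOKUP.update({"january": 1, "february": 2, "march": 3})

#: survey years with two-spotter planes (the era this analysis covers)
DEFAULT_YEARS = tuple(range(1993, 2001)) + tuple(range(2005, 2010))


def parse_month(value) -> int:
    """Accept 1-3, '1'-'3', 'Jan'/'January' etc.; return calendar month int."""
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _MONTH_LOOKUP:
            return _MONTH_LOOKUP[v]
        try:
            return int(v)
        except ValueError:
            raise ValidationError(f"unparseable month {value!r}") from None
    return int(value)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SurveyStratum:
    """A year:month:area cell of the stratification."""

    year: int
    month: int
    area: int


@dataclass
class SchoolObservation:
    """One school within a sighting, with per-observer biomass estimates.

    ``raw_estimates`` may be one-sided: trainee spotters did not estimate
    biomass, so flights with a trainee carry only the spotting pilot's
    estimate.
    """

    school_id: str
    sighting_id: str
    raw_estimates: dict[object, float]
    distance_nm: float

    def __post_init__(self):
        if not self.raw_estimates:
            raise ValidationError(f"school {self.school_id}: no biomass estimates")
        bad = {o: v for o, v in self.raw_estimates.items() if not v > 0}
        if bad:
            raise ValidationError(f"school {self.school_id}: non-positive estimates {bad}")
        if self.distance_nm < 0:
            raise ValidationError(f"school {self.school_id}: negative distance")


@dataclass
class SightingRecord:
    """One confirmed SBT sighting (>=1 schools) on a given flight."""

    sighting_id: str
    flight_key: tuple  # (year, month, day, plane)
    area: int
    schools: list[SchoolObservation]
    made_by: object = None  # spotter who first saw it, for efficiency calibration

    def __post_init__(self):
        if not self.schools:
            raise ValidationError(f"sighting {self.sighting_id} has no schools")
        for s in self.schools:
            if s.sighting_id != self.sighting_id:
                raise ValidationError(
                    f"school {s.school_id} carries sighting id {s.sighting_id}, "
                    f"expected {self.sighting_id}"
                )

    @property
    def min_distance_nm(self) -> float:
        return min(s.distance_nm for s in self.schools)


@dataclass
class EffortCell:
    """One flight x area aggregate: summed effort, counts, averaged conditions."""

    flight_key: tuple
    area: int
    distance_nm: float
    n_sightings: int
    env: dict[str, float]
    pair: tuple  # (pilot, spotter)

    def __post_init__(self):
        if not self.distance_nm > 0:
            raise ValidationError(f"effort cell {self.flight_key}/{self.area}: distance <= 0")
        if self.n_sightings < 0:
            raise ValidationError(f"effort cell {self.flight_key}/{self.area}: negative count")


@dataclass
class AreaWeights:
    """Relative geographical size of each analysis area; must sum to one."""

    w: dict[int, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.w.values()):
            raise SurveyConfigError("area weights must all be positive")
        total = sum(self.w.values())
        if abs(total - 1.0) > 1e-9:
            raise SurveyConfigError(f"area weights sum to {total}, expected 1")

    @classmethod
    def equal(cls, areas: Iterable[int]) -> "AreaWeights":
        areas = list(areas)
        # split 1.0 exactly despite floating division
        w = {a: 1.0 / len(areas) for a in areas}
        s = sum(w.values())
        w[areas[-1]] += 1.0 - s
        return cls(w)

    def __getitem__(self, area: int) -> float:
        return self.w[area]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: canonical column -> accepted aliases (matched case-insensitively)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "year": ("year", "yr", "survey_year"),
    "month": ("month", "mon"),
    "day": ("day",),
    "plane": ("plane", "plane_id"),
    "area": ("area", "area_id", "block"),
    "sighting_id": ("sighting_id", "sighting", "sight_id"),
    "school_id": ("school_id", "school"),
    "observer": ("observer", "observer_id", "spotter_id", "obs"),
    "biomass_t": ("biomass_t", "biomass", "tonnes", "size_t", "est_tonnes"),
    "distance_nm": ("distance_nm", "distance", "dist_nm", "dist"),
    "n_sightings": ("n_sightings", "nsight", "count", "n_sight"),
    "sst": ("sst", "sst_c", "sea_surface_temperature"),
    "wind": ("wind", "wind_speed", "windspeed", "wind_knots"),
    "haze": ("haze",),
    "swell": ("swell",),
    "shadow": ("shadow", "sea_shadow", "seashadow", "cloud"),
    "pilot": ("pilot", "spotting_pilot"),
    "spotter": ("spotter", "dedicated_spotter"),
    "made_by": ("made_by", "madeby", "seen_by"),
}


@dataclass
class SurveyConfig:
    """Validation and layout knobs shared by readers and the pipeline."""

    years: tuple[int, ...] = DEFAULT_YEARS
    months: tuple[int, ...] = (1, 2, 3)
    n_areas: int = 15
    strip_half_width_nm: float = 6.0
    area_weights: AreaWeights | None = None
    sst_bounds: tuple[float, float] = (5.0, 35.0)
    aliases: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_ALIASES))

    def __post_init__(self):
        if self.n_areas < 1:
            raise SurveyConfigError("n_areas must be >= 1")
        if self.strip_half_width_nm <= 0:
            raise SurveyConfigError("strip half-width must be positive")
        if self.area_weights is None:
            self.area_weights = AreaWeights.equal(range(1, self.n_areas + 1))
        missing = set(self.area_weights.w) - set(range(1, self.n_areas + 1))
        if missing:
            raise SurveyConfigError(f"weights given for unknown areas {sorted(missing)}")

    @property
    def areas(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_areas + 1))

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SurveyConfigError(f"unknown config keys: {sorted(unknown)}")
        if "area_weights" in raw and raw["area_weights"] is not None:
            raw["area_weights"] = AreaWeights({int(k): float(v) for k, v in raw["area_weights"].items()})
        for key in ("years", "months"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

ENV_COLUMNS = ("sst", "wind", "haze", "swell", "shadow")

SCHEMAS: dict[str, tuple[str, ...]] = {
    "bps_observer": ("sighting_id", "school_id", "observer", "biomass_t", "distance_nm"),
    "bps_glmm": ("sighting_id", "year", "month", "area", "sst", "biomass_t"),
    "spm_observer": ("year", "month", "day", "plane", "pilot", "spotter", "observer", "n_sightings"),
    "spm_glmm": ("year", "month", "day", "plane", "area", "pilot", "spotter",
                 "distance_nm", "n_sightings") + ENV_COLUMNS,
}

_INT_COLUMNS = {"year", "month", "day", "area", "n_sightings", "haze", "swell", "shadow"}
_FLOAT_COLUMNS = {"biomass_t", "distance_nm", "sst", "wind"}


def _resolve_columns(columns: Sequence[str], schema: str, aliases: Mapping[str, Sequence[str]]):
    lower = {c.lower().strip(): c for c in columns}
    mapping = {}
    for canon in SCHEMAS[schema]:
        for alias in aliases.get(canon, (canon,)):
            if alias.lower() in lower:
                mapping[lower[alias.lower()]] = canon
                break
        else:
            raise SchemaError(f"schema {schema!r}: mandatory column {canon!r} not found "
                              f"among {list(columns)}")
    return mapping


def _validate_frame(df: pd.DataFrame, schema: str, cfg: SurveyConfig) -> pd.DataFrame:
    """Type coercion and range checks; raises ValidationError with row numbers."""
    df = df.copy()
    if "month" in df.columns:
        df["month"] = df["month"].map(parse_month)
    for c in df.columns:
        if c in _INT_COLUMNS:
            df[c] = pd.to_numeric(df[c]).astype(int)
        elif c in _FLOAT_COLUMNS:
            df[c] = pd.to_numeric(df[c]).astype(float)

    def check(mask: pd.Series, what: str):
        if mask.any():
            raise ValidationError(f"schema {schema!r}: {what}",
                                  rows=[int(i) for i in df.index[mask]])

    if "year" in df.columns:
        check(~df["year"].isin(cfg.years), f"year outside configured set {cfg.years}")
    if "month" in df.columns:
        check(~df["month"].isin(cfg.months), "month outside the survey window")
    if "area" in df.columns:
        check(~df["area"].between(1, cfg.n_areas), f"area outside 1..{cfg.n_areas}")
    if "biomass_t" in df.columns:
        check(~(df["biomass_t"] > 0), "non-positive biomass")
    if "distance_nm" in df.columns:
        if schema == "bps_observer":
            check(df["distance_nm"] < 0, "negative perpendicular distance")
        else:
            check(~(df["distance_nm"] > 0), "non-positive search distance")
    if "n_sightings" in df.columns:
        check(df["n_sightings"] < 0, "negative sighting count")
    if "sst" in df.columns:
        lo, hi = cfg.sst_bounds
        check(~df["sst"].between(lo, hi), f"SST outside sanity window ({lo}, {hi})")
    if "wind" in df.columns:
        check(df["wind"] < 0, "negative wind speed")
    if "haze" in df.columns:
        check(~df["haze"].between(0, 3), "haze outside 0..3")
    if "swell" in df.columns:
        check(~df["swell"].between(0, 3), "swell outside 0..3")
    if "shadow" in df.columns:
        check(~df["shadow"].between(0, 8), "sea shadow outside 0..8")
    return df


def read_dataset(path, schema: str, cfg: SurveyConfig | None = None) -> pd.DataFrame:
    """Read one of the four survey CSV schemas into a validated DataFrame.

    Column names are resolved case-insensitively through ``cfg.aliases`` so
    files with different headings (e.g. ``Wind_speed`` vs ``wind``) load
    without editing.  Rows failing range checks raise :class:`ValidationError`
    with 0-based row numbers.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cfg = cfg or SurveyConfig()
    df = pd.read_csv(path)
    mapping = _resolve_columns(df.columns, schema, cfg.aliases)
    df = df.rename(columns=mapping)[list(SCHEMAS[schema])]
    return _validate_frame(df, schema, cfg).reset_index(drop=True)


def write_dataset(df: pd.DataFrame, path, schema: str) -> None:
    """Write a canonical-column DataFrame as one of the four schemas."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: frame lacks columns {missing}")
    out = df[list(SCHEMAS[schema])].copy()
    if "month" in out.columns:
        out["month"] = out["month"].map(parse_month)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def strip_filter(sightings: Sequence[SightingRecord],
                 half_width_nm: float = 6.0) -> list[SightingRecord]:
    """Keep sightings with at least one school inside the strip.

    Strip-transect rule: a sighting is retained iff the minimum perpendicular
    distance over its schools is <= ``half_width_nm``.  Retained sightings
    keep ALL their schools, including any beyond the strip edge — part of the
    sighting being in the strip is what makes it countable.
    """
    if half_width_nm <= 0:
        raise ValueError("half_width_nm must be positive")
    return [s for s in sightings if s.min_distance_nm <= half_width_nm]


def aggregate_effort(legs: pd.DataFrame,
                     sightings: Sequence[SightingRecord]) -> list[EffortCell]:
    """Accumulate per-leg effort into flight x area cells.

    ``legs`` has one row per searched leg with columns year, month, day,
    plane, area, pilot, spotter, distance_nm and the five environmental
    readings.  Within each flight-area combination distances are summed and
    environmental readings arithmetic-averaged; sighting counts are attached.
    Cells where effort was made but nothing was sighted are kept with
    ``n_sightings = 0`` — zero cells carry real information for the count
    model.  A sighting in a flight-area with no recorded effort is an error.
    """
    required = {"year", "month", "day", "plane", "area", "pilot", "spotter", "distance_nm"}
    missing = required - set(legs.columns)
    if missing:
        raise SchemaError(f"effort legs lack columns {sorted(missing)}")
    env_cols = [c for c in ENV_COLUMNS if c in legs.columns]

    counts: dict[tuple, int] = {}
    for s in sightings:
        counts[(s.flight_key, s.area)] = counts.get((s.flight_key, s.area), 0) + 1

    cells = []
    key_cols = ["year", "month", "day", "plane", "area"]
    grouped = legs.groupby(key_cols, sort=True)
    seen = set()
    for (year, month, day, plane, area), grp in grouped:
        fkey = (int(year), int(month), int(day), plane)
        pairs = set(zip(grp["pilot"], grp["spotter"]))
        if len(pairs) != 1:
            raise ValidationError(f"flight {fkey} area {area}: multiple observer pairs {pairs}")
        env = {c: float(grp[c].mean()) for c in env_cols}
        cells.append(EffortCell(
            flight_key=fkey,
            area=int(area),
            distance_nm=float(grp["distance_nm"].sum()),
            n_sightings=counts.get((fkey, int(area)), 0),
            env=env,
            pair=next(iter(pairs)),
        ))
        seen.add((fkey, int(area)))

    orphans = sorted(set(counts) - seen, key=repr)
    if orphans:
        raise ValidationError(f"sightings in flight-areas with no recorded effort: {orphans}")
    return cells


def effort_cells_to_frame(cells: Sequence[EffortCell]) -> pd.DataFrame:
    """EffortCell list -> spm_glmm-schema DataFrame."""
    rows = []
    for c in cells:
        year, month, day, plane = c.flight_key
        rows.append({
            "year": year, "month": month, "day": day, "plane": plane,
            "area": c.area, "pilot": c.pair[0], "spotter": c.pair[1],
            "distance_nm": c.distance_nm, "n_sightings": c.n_sightings,
            **{k: c.env.get(k, np.nan) for k in ENV_COLUMNS},
        })
    return pd.DataFrame(rows, columns=list(SCHEMAS["spm_glmm"]))


def effort_cells_from_frame(df: pd.DataFrame) -> list[EffortCell]:
    """spm_glmm-schema DataFrame -> EffortCell list (inverse of the above)."""
    cells = []
    for _, r in df.iterrows():
        cells.append(EffortCell(
            flight_key=(int(r["year"]), int(r["month"]), int(r["day"]), r["plane"]),
            area=int(r["area"]),
            distance_nm=float(r["distance_nm"]),
            n_sightings=int(r["n_sightings"]),
            env={k: float(r[k]) for k in ENV_COLUMNS},
            pair=(r["pilot"], r["spotter"]),
        ))
    return cells


def sightings_rate_per_100nm(n_sightings: int, distance_nm: float) -> float:
    """Sightings per 100 nm of transect searched."""
    if not distance_nm > 0:
        raise ValueError("distance_nm must be positive")
    if n_sightings < 0:
        raise ValueError("n_sightings must be >= 0")
    return 100.0 * n_sightings / distance_nm
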