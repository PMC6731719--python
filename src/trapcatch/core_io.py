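"""Domain types, CSV readers/writers, validation and sample-exclusion filters.

A campaign is four tables: trap sites (with a five-level forest-type label),
trap-centred tree transects (the raw material of the dead-wood covariate),
daily weather, and trap-service samples carrying per-species counts. The
unit of observation downstream is the sample: one trap-service interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Trap days per reported "trap month" (logging only; the model never uses it).
DAYS_PER_TRAP_MONTH = 30.5


class SchemaError(ValueError):
    """A CSV is missing a required column or has an unexpected one."""


class ValidationError(ValueError):
    """A dataset breaks an invariant (referential integrity, ranges, ...)."""


class ForestType(str, Enum):
    """Successional habitat class of a trap location."""

    PRIMARY = "primary"
    SWAMP = "swamp"
    DISTURBED = "disturbed"
    CLEARCUT = "clearcut"
    FARM = "farm"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FOREST_TYPES: tuple[ForestType, ...] = tuple(ForestType)

#: Dummy-coded forest levels, in fixed design order; primary is the reference.
NON_REFERENCE_TYPES: tuple[ForestType, ...] = (
    ForestType.SWAMP,
    ForestType.DISTURBED,
    ForestType.CLEARCUT,
    ForestType.FARM,
)


@dataclass(frozen=True)
class TrapSite:
    trap_id: str
    site_code: str
    forest_type: ForestType
    orientation_deg: float | None = None
    canopy_openness_pct: float | None = None

    def __post_init__(self) -> None:
        if self.orientation_deg is not None and not 0 <= self.orientation_deg <= 360:
            raise ValidationError(
                f"trap {self.trap_id}: orientation_deg {self.orientation_deg} outside [0, 360]"
            )
        if self.canopy_openness_pct is not None and not 0 <= self.canopy_openness_pct <= 100:
            raise ValidationError(
                f"trap {self.trap_id}: canopy_openness_pct {self.canopy_openness_pct} outside [0, 100]"
            )


class TreeStatus(str, Enum):
    ALIVE = "alive"
    DEAD = "dead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TreeRecord:
    """One tree (dbh >= 5 cm) in one of the two 50 x 2.5 m transects at a trap.

    Dead trees carry a three-point decay level (1 barely dead, 2 light decay,
    3 clearly decaying); only level 3 contributes to the dead-wood score.
    """

    trap_id: str
    transect_id: int
    dbh_cm: float
    distance_m: float
    status: TreeStatus
    decay_level: int | None = None
    species_name: str | None = None

    def __post_init__(self) -> None:
        if self.transect_id not in (1, 2):
            raise ValidationError(f"trap {self.trap_id}: transect_id must be 1 or 2")
        if not self.dbh_cm > 0:
            raise ValidationError(f"trap {self.trap_id}: dbh_cm must be positive")
        if not self.distance_m > 0:
            raise ValidationError(f"trap {self.trap_id}: distance_m must be positive")
        if self.status is TreeStatus.DEAD:
            if self.decay_level not in (1, 2, 3):
                raise ValidationError(
                    f"trap {self.trap_id}: dead tree needs decay_level in {{1,2,3}}"
                )
        elif self.decay_level is not None:
            raise ValidationError(
                f"trap {self.trap_id}: living tree must not carry a decay_level"
            )


@dataclass(frozen=True)
class WeatherDay:
    date: Date
    rain_mm: float
    tmin_c: float | None = None
    tmax_c: float | None = None

    def __post_init__(self) -> None:
        if self.rain_mm < 0:
            raise ValidationError(f"{self.date}: rain_mm must be non-negative")
        if self.tmin_c is not None and self.tmax_c is not None and self.tmin_c > self.tmax_c:
            raise ValidationError(f"{self.date}: tmin_c exceeds tmax_c")


@dataclass(frozen=True)
class SampleRecord:
    """One trap-service interval with its per-species counts.

    Effort is the fractional number of days between mounting and emptying
    the collecting head; `usable` is False for samples judged
    unrepresentative of a normal catch (damaged, partly eaten, ...).
    """

    sample_id: str
    trap_id: str
    start: datetime
    end: datetime
    usable: bool
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(f"sample {self.sample_id}: end must be after start")
        for sp, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"sample {self.sample_id}: count for {sp} must be a non-negative integer"
                )

    @property
    def effort_days(self) -> float:
        """Sampling effort in fractional days."""
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class Dataset:
    trap_sites: list[TrapSite]
    trees: list[TreeRecord]
    weather: list[WeatherDay]
    samples: list[SampleRecord]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            seen: dict[str, None] = {}
            for s in self.samples:
                for sp in s.counts:
                    seen.setdefault(sp)
            self.species = list(seen)
        self.validate()

    def validate(self) -> None:
        trap_ids = [t.trap_id for t in self.trap_sites]
        if len(set(trap_ids)) != len(trap_ids):
            dupes = sorted({t for t in trap_ids if trap_ids.count(t) > 1})
            raise ValidationError(f"duplicate trap_id(s): {dupes}")
        known = set(trap_ids)
        bad = sorted({s.trap_id for s in self.samples if s.trap_id not in known})
        if bad:
            raise ValidationError(f"samples reference unknown trap_id(s): {bad}")
        bad = sorted({t.trap_id for t in self.trees if t.trap_id not in known})
        if bad:
            raise ValidationError(f"trees reference unknown trap_id(s): {bad}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        declared = set(self.species)
        for s in self.samples:
            unknown = set(s.counts) - declared
            if unknown:
                raise ValidationError(
                    f"sample {s.sample_id}: counts for undeclared species {sorted(unknown)}"
                )
        dates = [w.date for w in self.weather]
        if len(set(dates)) != len(dates):
            raise ValidationError("duplicate weather dates")
        if dates:
            ordered = sorted(dates)
            gaps = [
                d
                for prev, d in zip(ordered, ordered[1:])
                if (d - prev).days != 1
            ]
            if gaps:
                raise ValidationError(
                    f"weather dates are not a single contiguous run; gap(s) before {gaps[:5]}"
                )

    @property
    def weather_by_date(self) -> dict[Date, WeatherDay]:
        return {w.date: w for w in self.weather}

    def trap_site_map(self) -> dict[str, TrapSite]:
        return {t.trap_id: t for t in self.trap_sites}

    def total_effort_days(self) -> float:
        return sum(s.effort_days for s in self.samples)


# ---------------------------------------------------------------------------
# CSV schemas

_SITE_COLS = ["trap_id", "site_code", "forest_type", "orientation_deg", "canopy_openness_pct"]
_TREE_COLS = ["trap_id", "transect_id", "species_name", "dbh_cm", "distance_m", "status", "decay_level"]
_WEATHER_COLS = ["date", "rain_mm", "tmin_c", "tmax_c"]
_SAMPLE_FIXED_COLS = ["sample_id", "trap_id", "start", "end", "usable"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)  # type: ignore[arg-type]


def _parse_dt(value: object, path: Path, row: int) -> datetime:
    try:
        ts = pd.Timestamp(value)  # type: ignore[arg-type]
        if pd.isna(ts):
            raise ValueError("missing")
        return ts.to_pydatetime()
    except Exception as exc:
        raise SchemaError(f"{path}: row {row}: unparseable datetime {value!r}") from exc


def read_dataset(
    sites: str | Path,
    trees: str | Path,
    weather: str | Path,
    samples: str | Path,
    species: Sequence[str] | None = None,
) -> Dataset:
    """Read the four campaign CSVs into a validated :class:`Dataset`.

    Parameters
    ----------
    sites, trees, weather, samples
        Paths to the four tables (see the documented headers).
    species
        Optional declared species list. When given, sample columns must be a
        subset of it (unknown columns are an error, protecting against
        typos) and absent species become structural zeros. When omitted the
        species list is taken from the sample-table header.
    """
    sites_p, trees_p, weather_p, samples_p = (Path(p) for p in (sites, trees, weather, samples))

    sdf = pd.read_csv(sites_p, dtype={"trap_id": str, "site_code": str})
    _require_columns(sdf, _SITE_COLS[:3], sites_p)
    trap_sites = []
    for i, row in enumerate(sdf.itertuples(index=False), start=2):
        try:
            trap_sites.append(
                TrapSite(
                    trap_id=str(row.trap_id),
                    site_code=str(row.site_code),
                    forest_type=ForestType(str(row.forest_type)),
                    orientation_deg=_opt_float(getattr(row, "orientation_deg", None)),
                    canopy_openness_pct=_opt_float(getattr(row, "canopy_openness_pct", None)),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{sites_p}: row {i}: {exc}") from exc

    tdf = pd.read_csv(trees_p, dtype={"trap_id": str, "species_name": str})
    _require_columns(tdf, [c for c in _TREE_COLS if c != "species_name"], trees_p)
    trees_out = []
    for i, row in enumerate(tdf.itertuples(index=False), start=2):
        try:
            decay = row.decay_level
            decay_i = None if pd.isna(decay) else int(decay)
            name = getattr(row, "species_name", None)
            trees_out.append(
                TreeRecord(
                    trap_id=str(row.trap_id),
                    transect_id=int(row.transect_id),
                    species_name=None if name is None or pd.isna(name) else str(name),
                    dbh_cm=float(row.dbh_cm),
                    distance_m=float(row.distance_m),
                    status=TreeStatus(str(row.status)),
                    decay_level=decay_i,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{trees_p}: row {i}: {exc}") from exc

    wdf = pd.read_csv(weather_p)
    _require_columns(wdf, _WEATHER_COLS[:2], weather_p)
    weather_out = []
    for i, row in enumerate(wdf.itertuples(index=False), start=2):
        try:
            weather_out.append(
                WeatherDay(
                    date=pd.Timestamp(row.date).date(),
                    rain_mm=float(row.rain_mm),
                    tmin_c=_opt_float(getattr(row, "tmin_c", None)),
                    tmax_c=_opt_float(getattr(row, "tmax_c", None)),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{weather_p}: row {i}: {exc}") from exc

    mdf = pd.read_csv(samples_p, dtype={"sample_id": str, "trap_id": str})
    _require_columns(mdf, _SAMPLE_FIXED_COLS, samples_p)
    count_cols = [c for c in mdf.columns if c not in _SAMPLE_FIXED_COLS]
    if species is not None:
        unknown = [c for c in count_cols if c not in species]
        if unknown:
            raise SchemaError(f"{samples_p}: unknown species column(s) {unknown}")
        species_list = list(species)
    else:
        species_list = count_cols
    samples_out = []
    records = mdf.to_dict("records")
    for i, rec in enumerate(records, start=2):
        counts: dict[str, int] = {}
        for sp in count_cols:
            val = rec[sp]
            try:
                if pd.isna(val) or int(val) != float(val):
                    raise ValueError(val)
                counts[sp] = int(val)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{samples_p}: row {i}: unparseable count {val!r} for {sp}") from exc
        for sp in species_list:
            counts.setdefault(sp, 0)
        usable_raw = str(rec["usable"]).strip().lower()
        if usable_raw not in {"true", "false", "1", "0"}:
            raise SchemaError(f"{samples_p}: row {i}: unparseable usable flag {rec['usable']!r}")
        samples_out.append(
            SampleRecord(
                sample_id=str(rec["sample_id"]),
                trap_id=str(rec["trap_id"]),
                start=_parse_dt(rec["start"], samples_p, i),
                end=_parse_dt(rec["end"], samples_p, i),
                usable=usable_raw in {"true", "1"},
                counts=counts,
            )
        )

    return Dataset(
        trap_sites=trap_sites,
        trees=trees_out,
        weather=weather_out,
        samples=samples_out,
        species=species_list,
    )


def write_dataset(
    dataset: Dataset,
    sites: str | Path,
    trees: str | Path,
    weather: str | Path,
    samples: str | Path,
) -> None:
    """Write the four campaign CSVs; output is byte-stable under round-trips.

    Counts are serialised one column per species with explicit zeros, so a
    sample table is self-describing.
    """
    def fmt_opt(x: float | None) -> str:
        return "" if x is None else format(x, "g")

    pd.DataFrame(
        [
            {
                "trap_id": t.trap_id,
                "site_code": t.site_code,
                "forest_type": t.forest_type.value,
                "orientation_deg": fmt_opt(t.orientation_deg),
                "canopy_openness_pct": fmt_opt(t.canopy_openness_pct),
            }
            for t in dataset.trap_sites
        ],
        columns=_SITE_COLS,
    ).to_csv(sites, index=False)

    pd.DataFrame(
        [
            {
                "trap_id": t.trap_id,
                "transect_id": t.transect_id,
                "species_name": "" if t.species_name is None else t.species_name,
                "dbh_cm": format(t.dbh_cm, "g"),
                "distance_m": format(t.distance_m, "g"),
                "status": t.status.value,
                "decay_level": "" if t.decay_level is None else t.decay_level,
            }
            for t in dataset.trees
        ],
        columns=_TREE_COLS,
    ).to_csv(trees, index=False)

    pd.DataFrame(
        [
            {
                "date": w.date.isoformat(),
                "rain_mm": format(w.rain_mm, "g"),
                "tmin_c": fmt_opt(w.tmin_c),
                "tmax_c": fmt_opt(w.tmax_c),
            }
            for w in dataset.weather
        ],
        columns=_WEATHER_COLS,
    ).to_csv(weather, index=False)

    cols = _SAMPLE_FIXED_COLS + list(dataset.species)
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "trap_id": s.trap_id,
                "start": s.start.isoformat(timespec="minutes"),
                "end": s.end.isoformat(timespec="minutes"),
                "usable": s.usable,
                **{sp: int(s.counts.get(sp, 0)) for sp in dataset.species},
            }
            for s in dataset.samples
        ],
        columns=cols,
    ).to_csv(samples, index=False)


def _covered_days(start: datetime, end: datetime) -> list[Date]:
    """Calendar days whose [00:00, 24:00) window intersects [start, end)."""
    days = []
    d = start.date()
    while datetime(d.year, d.month, d.day) < end:
        days.append(d)
        d = d + timedelta(days=1)
    return days


def filter_samples(dataset: Dataset, weather_required: bool = True) -> Dataset:
    """Drop unusable samples, and optionally samples without weather coverage.

    Samples flagged ``usable = False`` (unrepresentative catches) are always
    dropped. With ``weather_required`` every calendar day intersecting the
    service interval must be present in the weather table, mirroring the
    exclusion of late-campaign samples once station records stop. One line
    per dropped sample is logged with its reason; the operation is
    idempotent.
    """
    have = {w.date for w in dataset.weather}
    kept: list[SampleRecord] = []
    n_unusable = 0
    n_uncovered = 0
    for s in dataset.samples:
        if not s.usable:
            logger.info("dropping sample %s: flagged unusable", s.sample_id)
            n_unusable += 1
            continue
        if weather_required:
            missing = [d for d in _covered_days(s.start, s.end) if d not in have]
            if missing:
                logger.info(
                    "dropping sample %s: no weather for %s", s.sample_id, missing[0]
                )
                n_uncovered += 1
                continue
        kept.append(s)
    dropped = n_unusable + n_uncovered
    assert len(kept) + dropped == len(dataset.samples)
    if not kept:
        logger.warning("filter_samples retained no samples")
    effort = sum(s.effort_days for s in kept)
    logger.info(
        "retained %d of %d samples (%.2f trap days, ~%.0f trap months); "
        "dropped %d unusable, %d without weather coverage",
        len(kept), len(dataset.samples), effort, effort / DAYS_PER_TRAP_MONTH,
        n_unusable, n_uncovered,
    )
    return replace(dataset, samples=kept)
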