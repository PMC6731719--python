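"""Model covariates and the per-sample design.

Four covariates drive the catch model: *date* (days from a campaign
reference to the midpoint of the service interval), *rain* (mean daily
rainfall over the interval), *dead wood* (a trap-level score summing
dbh²/distance over clearly decaying trees in the two transects) and
*forest type* (dummy-coded, primary forest as reference). Sampling effort
in days enters the model as a log offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trapcatch.core_io import (
    Dataset,
    ForestType,
    NON_REFERENCE_TYPES,
    SampleRecord,
    TreeRecord,
    TreeStatus,
    ValidationError,
    WeatherDay,
    _covered_days,
)

logger = logging.getLogger(__name__)

#: Default campaign reference instant for the date covariate.
DEFAULT_REFERENCE = datetime(2014, 9, 1, 0, 0)

#: Fixed design column order (dummy coding, primary forest as reference).
DESIGN_COLUMNS: tuple[str, ...] = (
    "intercept",
    "date",
    "rain",
    "deadwood",
    "swamp",
    "disturbed",
    "clearcut",
    "farm",
)


class CoverageError(ValueError):
    """A sample's service interval is not fully covered by weather records."""


def deadwood_score(
    trees: Iterable[TreeRecord],
    dbh_unit: str = "m",
) -> float:
    """Dead-wood score for one trap: Σ dbh²/distance over clearly decaying trees.

    Only dead trees at decay level 3 contribute; barely dead or lightly
    decayed trees and living trees are ignored. Large trunks close to the
    trap dominate the score.

    Parameters
    ----------
    trees
        Transect records, all belonging to the same trap.
    dbh_unit
        ``"m"`` (default) converts dbh from the recorded cm to metres before
        squaring, giving scores of order 0.1–1 for forest traps; ``"cm"``
        keeps dbh in cm (scores 10⁴ times larger). The two conventions
        rescale the fitted dead-wood coefficient by the same factor.
    """
    if dbh_unit not in ("m", "cm"):
        raise ValueError(f"dbh_unit must be 'm' or 'cm', got {dbh_unit!r}")
    scale = 1e-4 if dbh_unit == "m" else 1.0
    total = 0.0
    for t in trees:
        if t.distance_m == 0:
            raise ValidationError(f"trap {t.trap_id}: tree at distance 0 (degenerate geometry)")
        if t.status is TreeStatus.DEAD and t.decay_level == 3:
            total += scale * t.dbh_cm**2 / t.distance_m
    return total


def date_covariate(sample: SampleRecord, reference: datetime = DEFAULT_REFERENCE) -> float:
    """Days from the reference instant to the midpoint of the service interval.

    Negative for samples collected before the reference.
    """
    midpoint = sample.start + (sample.end - sample.start) / 2
    return (midpoint - reference).total_seconds() / 86400.0


def rain_covariate(sample: SampleRecord, weather: Iterable[WeatherDay]) -> float:
    """Mean daily rainfall (mm·day⁻¹) over the service interval.

    Averages the daily totals of every calendar day whose [00:00, 24:00)
    window intersects [start, end); partial first and last days count
    fully. Raises :class:`CoverageError` naming the first uncovered day.
    """
    by_date = {w.date: w.rain_mm for w in weather}
    vals = []
    for d in _covered_days(sample.start, sample.end):
        if d not in by_date:
            raise CoverageError(f"sample {sample.sample_id}: no weather record for {d}")
        vals.append(by_date[d])
    return float(np.mean(vals))


@dataclass(frozen=True)
class DesignRow:
    """Covariates and counts for one retained sample."""

    sample_id: str
    trap_id: str
    site_code: str
    days: float
    date: float
    rain: float
    deadwood: float
    forest_type: ForestType
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.days > 0:
            raise ValidationError(f"sample {self.sample_id}: effort days must be positive")
        if self.rain < 0 or self.deadwood < 0:
            raise ValidationError(f"sample {self.sample_id}: rain and deadwood must be >= 0")


@dataclass
class DesignMatrix:
    """The fitted design: one row per sample, fixed column order.

    Forest type is dummy-coded with primary forest as the all-zero
    reference, so a species' primary-forest coefficient is identically 0.
    """

    rows: list[DesignRow]
    species: list[str]
    reference_datetime: datetime = DEFAULT_REFERENCE
    columns: tuple[str, ...] = field(default=DESIGN_COLUMNS, init=False)

    def __len__(self) -> int:
        return len(self.rows)

    def model_matrix(self) -> np.ndarray:
        """(n, 8) array in :data:`DESIGN_COLUMNS` order."""
        X = np.zeros((len(self.rows), len(DESIGN_COLUMNS)))
        dummy_idx = {ft.value: DESIGN_COLUMNS.index(ft.value) for ft in NON_REFERENCE_TYPES}
        for i, r in enumerate(self.rows):
            X[i, 0] = 1.0
            X[i, 1] = r.date
            X[i, 2] = r.rain
            X[i, 3] = r.deadwood
            j = dummy_idx.get(r.forest_type.value)
            if j is not None:
                X[i, j] = 1.0
        return X

    def offsets(self) -> np.ndarray:
        """Log effort-days offset vector."""
        return np.log(np.array([r.days for r in self.rows]))

    def counts_matrix(self) -> np.ndarray:
        """(n, n_species) integer count matrix, species in declared order."""
        return np.array([r.counts for r in self.rows], dtype=np.int64).reshape(
            len(self.rows), len(self.species)
        )

    def site_codes(self) -> list[str]:
        return [r.site_code for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "sample_id": r.sample_id,
                "trap_id": r.trap_id,
                "site_code": r.site_code,
                "days": r.days,
                "date": r.date,
                "rain": r.rain,
                "deadwood": r.deadwood,
                "forest_type": r.forest_type.value,
                **{sp: r.counts[k] for k, sp in enumerate(self.species)},
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str | Path, reference: datetime = DEFAULT_REFERENCE) -> "DesignMatrix":
        df = pd.read_csv(path, dtype={"sample_id": str, "trap_id": str, "site_code": str})
        fixed = ["sample_id", "trap_id", "site_code", "days", "date", "rain", "deadwood", "forest_type"]
        missing = [c for c in fixed if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing design column(s) {missing}")
        species = [c for c in df.columns if c not in fixed]
        rows = [
            DesignRow(
                sample_id=rec["sample_id"],
                trap_id=rec["trap_id"],
                site_code=rec["site_code"],
                days=float(rec["days"]),
                date=float(rec["date"]),
                rain=float(rec["rain"]),
                deadwood=float(rec["deadwood"]),
                forest_type=ForestType(rec["forest_type"]),
                counts=tuple(int(rec[sp]) for sp in species),
            )
            for rec in df.to_dict("records")
        ]
        return cls(rows=rows, species=species, reference_datetime=reference)

    def subset(self, indices: Sequence[int]) -> "DesignMatrix":
        return DesignMatrix(
            rows=[self.rows[i] for i in indices],
            species=list(self.species),
            reference_datetime=self.reference_datetime,
        )

    def with_counts(self, counts: np.ndarray) -> "DesignMatrix":
        """Same design with a replacement count matrix (for resampling)."""
        from dataclasses import replace as dc_replace

        if counts.shape != (len(self.rows), len(self.species)):
            raise ValueError("replacement count matrix has wrong shape")
        rows = [
            dc_replace(r, counts=tuple(int(c) for c in counts[i]))
            for i, r in enumerate(self.rows)
        ]
        return DesignMatrix(rows=rows, species=list(self.species),
                            reference_datetime=self.reference_datetime)


def assemble_design(
    dataset: Dataset,
    reference: datetime = DEFAULT_REFERENCE,
    dbh_unit: str = "m",
) -> DesignMatrix:
    """Build the per-sample design from a filtered dataset.

    The dead-wood score is computed once per trap and broadcast to its
    samples; a trap with no transect records scores 0 with a logged warning
    (absent data is only distinguishable from a genuine 0 via that
    warning). Expects a dataset already passed through
    :func:`~trapcatch.core_io.filter_samples` with weather required.
    """
    site_map = dataset.trap_site_map()
    trees_by_trap: dict[str, list[TreeRecord]] = {}
    for t in dataset.trees:
        trees_by_trap.setdefault(t.trap_id, []).append(t)
    scores: dict[str, float] = {}
    for trap_id in site_map:
        recs = trees_by_trap.get(trap_id)
        if recs is None:
            logger.warning("trap %s has no tree records; dead-wood score set to 0", trap_id)
            scores[trap_id] = 0.0
        else:
            scores[trap_id] = deadwood_score(recs, dbh_unit=dbh_unit)

    rows = []
    for s in dataset.samples:
        site = site_map[s.trap_id]
        rows.append(
            DesignRow(
                sample_id=s.sample_id,
                trap_id=s.trap_id,
                site_code=site.site_code,
                days=s.effort_days,
                date=date_covariate(s, reference),
                rain=rain_covariate(s, dataset.weather),
                deadwood=scores[s.trap_id],
                forest_type=site.forest_type,
                counts=tuple(int(s.counts.get(sp, 0)) for sp in dataset.species),
            )
        )
    return DesignMatrix(rows=rows, species=list(dataset.species), reference_datetime=reference)
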