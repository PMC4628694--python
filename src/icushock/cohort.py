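"""Patient data model, long-format cohort file I/O, and inclusion criteria.

The cohort lives in three delimited text files:

* ``vitals``   — ``patient_id,variable,time_h,value`` with ``variable`` drawn
  from the 15 canonical names in :data:`CANONICAL_VARIABLES`;
* ``fluids``   — ``patient_id,time_h,volume_ml`` (intravenous volume events);
* ``outcomes`` — ``patient_id,age_years,icu_stay_h,death_time_h`` where
  ``death_time_h`` is empty for patients not known to have died.

All times are hours from ICU admission, as floating-point values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical variable names, in the order levels are reported.
CANONICAL_VARIABLES: tuple[str, ...] = (
    "SBP", "DBP", "MAP", "HR", "RR", "CVP", "CO",
    "T", "pH", "creatinine", "glucose", "lactate",
    "hematocrit", "WBC", "SpO2",
)

#: Units of each canonical variable.
VARIABLE_UNITS: dict[str, str] = {
    "SBP": "mmHg", "DBP": "mmHg", "MAP": "mmHg", "HR": "bpm",
    "RR": "breaths/min", "CVP": "mmHg", "CO": "L/min", "T": "degC",
    "pH": "units", "creatinine": "mg/dL", "glucose": "mg/dL",
    "lactate": "mmol/L", "hematocrit": "%", "WBC": "cells/cmm",
    "SpO2": "%",
}


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the long-format contract."""


@dataclass(frozen=True)
class VitalSeries:
    """An irregularly sampled series of one variable for one patient."""

    variable: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.variable not in CANONICAL_VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(times) != len(values):
            raise ValueError(
                f"{self.variable}: {len(times)} times but {len(values)} values"
            )
        if len(times) and times[0] < 0:
            raise ValueError(f"{self.variable}: negative timestamp {times[0]}")
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"{self.variable}: times must be strictly increasing"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError(f"{self.variable}: non-finite entries")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FluidEvent:
    """A single intravenous fluid-volume event."""

    time: float
    volume: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"fluid event time {self.time} < 0")
        if self.volume < 0:
            raise ValueError(f"fluid event volume {self.volume} < 0")


@dataclass
class PatientRecord:
    """All series, fluid events, stay length and outcome for one patient."""

    patient_id: str
    series: dict[str, VitalSeries] = field(default_factory=dict)
    fluids: list[FluidEvent] = field(default_factory=list)
    icu_stay_h: float = 0.0
    death_time_h: float | None = None
    age_years: float = 18.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.icu_stay_h <= 0:
            raise ValueError(f"{self.patient_id}: icu_stay_h must be > 0")
        if self.death_time_h is not None and self.death_time_h < 0:
            raise ValueError(f"{self.patient_id}: death_time_h < 0")
        if self.age_years < 18:
            raise ValueError(f"{self.patient_id}: age_years must be >= 18")
        for name, s in self.series.items():
            if name != s.variable:
                raise ValueError(
                    f"{self.patient_id}: series key {name!r} != {s.variable!r}"
                )
            if len(s) and s.times[-1] > self.icu_stay_h:
                raise ValueError(
                    f"{self.patient_id}: {name} sample at {s.times[-1]} h "
                    f"beyond ICU stay of {self.icu_stay_h} h"
                )
        for ev in self.fluids:
            if ev.volume < 0 or ev.time < 0:
                raise ValueError(
                    f"{self.patient_id}: invalid fluid event {ev}")

    def n_values(self, variable: str) -> int:
        """Number of measurements of ``variable`` (0 if absent)."""
        s = self.series.get(variable)
        return 0 if s is None else len(s)


@dataclass(frozen=True)
class InclusionReport:
    patient_id: str
    included: bool
    failed_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.included != (len(self.failed_rules) == 0):
            raise ValueError("included must match emptiness of failed_rules")


#: (rule name, variable, minimum count) gates for inclusion.
_COUNT_RULES: tuple[tuple[str, str, int], ...] = (
    ("min_hr_count", "HR", 10),
    ("min_t_count", "T", 10),
    ("min_sbp_count", "SBP", 10),
    ("min_rr_count", "RR", 10),
    ("min_wbc_count", "WBC", 2),
)

MIN_STAY_H = 48.0


def apply_inclusion_criteria(record: PatientRecord) -> InclusionReport:
    """Check the cohort gates: measurement counts and minimum ICU stay.

    A patient is included iff HR, T, SBP and RR each have at least 10
    measurements, WBC has at least 2, and the ICU stay is at least 48 h.
    Missing series count as zero measurements.
    """
    failed: list[str] = []
    for rule, variable, minimum in _COUNT_RULES:
        if record.n_values(variable) < minimum:
            failed.append(rule)
    if record.icu_stay_h < MIN_STAY_H:
        failed.append("min_icu_stay")
    return InclusionReport(record.patient_id, not failed, tuple(failed))


def filter_cohort(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], list[InclusionReport]]:
    """Apply :func:`apply_inclusion_criteria` to every record.

    Returns the included records plus the full per-patient report list.
    """
    reports = [apply_inclusion_criteria(r) for r in records]
    by_id = {rep.patient_id: rep for rep in reports}
    kept = [r for r in records if by_id[r.patient_id].included]
    return kept, reports


# ---------------------------------------------------------------------------
# file I/O

_VITALS_COLS = ["patient_id", "variable", "time_h", "value"]
_FLUIDS_COLS = ["patient_id", "time_h", "volume_ml"]
_OUTCOMES_COLS = ["patient_id", "age_years", "icu_stay_h", "death_time_h"]


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    if list(df.columns) != list(columns):
        raise CohortFormatError(
            f"{path}: expected header {','.join(columns)}, "
            f"got {','.join(df.columns)}"
        )
    return df


def _check_numeric(df: pd.DataFrame, col: str, path: Path,
                   allow_na: bool = False) -> None:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna() if allow_na else coerced.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise CohortFormatError(
            f"{path}: line {line}: field {col!r} is not numeric "
            f"({df[col].iloc[line - 2]!r})"
        )


def read_cohort(
    vitals_path: str | Path,
    fluids_path: str | Path,
    outcomes_path: str | Path,
) -> list[PatientRecord]:
    """Read the three long-format cohort files into patient records.

    One record is produced per distinct ``patient_id`` in the outcomes file;
    series are sorted by time.  Unknown variable names, duplicated
    (patient, variable, time) rows, and malformed fields raise
    :class:`CohortFormatError` naming the file and line.
    """
    vitals_path, fluids_path, outcomes_path = (
        Path(vitals_path), Path(fluids_path), Path(outcomes_path))
    vitals = _read_table(vitals_path, _VITALS_COLS)
    fluids = _read_table(fluids_path, _FLUIDS_COLS)
    outcomes = _read_table(outcomes_path, _OUTCOMES_COLS)

    unknown = ~vitals["variable"].isin(CANONICAL_VARIABLES)
    if unknown.any():
        line = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
        raise CohortFormatError(
            f"{vitals_path}: line {line}: unknown variable "
            f"{vitals['variable'].iloc[line - 2]!r}"
        )
    _check_numeric(vitals, "time_h", vitals_path)
    _check_numeric(vitals, "value", vitals_path)
    dup = vitals.duplicated(subset=["patient_id", "variable", "time_h"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise CohortFormatError(
            f"{vitals_path}: line {line}: duplicated (patient, variable, time)"
        )
    _check_numeric(fluids, "time_h", fluids_path)
    _check_numeric(fluids, "volume_ml", fluids_path)
    for col in ("age_years", "icu_stay_h"):
        _check_numeric(outcomes, col, outcomes_path)
    _check_numeric(outcomes, "death_time_h", outcomes_path, allow_na=True)
    dup = outcomes.duplicated(subset=["patient_id"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise CohortFormatError(
            f"{outcomes_path}: line {line}: duplicated patient_id")

    orphans = set(vitals["patient_id"]) - set(outcomes["patient_id"])
    if orphans:
        raise CohortFormatError(
            f"{vitals_path}: patients {sorted(orphans)} missing from "
            f"{outcomes_path}"
        )

    records: list[PatientRecord] = []
    v_groups = dict(tuple(vitals.groupby("patient_id", sort=False)))
    f_groups = dict(tuple(fluids.groupby("patient_id", sort=False)))
    for row in outcomes.itertuples(index=False):
        pid = row.patient_id
        series: dict[str, VitalSeries] = {}
        pv = v_groups.get(pid)
        if pv is not None:
            for var, grp in pv.groupby("variable", sort=False):
                grp = grp.sort_values("time_h")
                series[var] = VitalSeries(
                    var,
                    grp["time_h"].to_numpy(float),
                    grp["value"].to_numpy(float),
                )
        fl: list[FluidEvent] = []
        pf = f_groups.get(pid)
        if pf is not None:
            pf = pf.sort_values("time_h")
            fl = [FluidEvent(float(t), float(v))
                  for t, v in zip(pf["time_h"], pf["volume_ml"])]
        death = None if pd.isna(row.death_time_h) else float(row.death_time_h)
        records.append(PatientRecord(
            patient_id=pid,
            series=series,
            fluids=fl,
            icu_stay_h=float(row.icu_stay_h),
            death_time_h=death,
            age_years=float(row.age_years),
        ))
    return records


def write_cohort(
    records: Iterable[PatientRecord],
    vitals_path: str | Path,
    fluids_path: str | Path,
    outcomes_path: str | Path,
) -> None:
    """Write records to the three cohort files, deterministically ordered.

    Rows are sorted by (patient, variable, time); the result round-trips
    through :func:`read_cohort` field-for-field.
    """
    records = list(records)
    for rec in records:
        rec.validate()  # catch post-construction mutation before writing
    var_order = {v: i for i, v in enumerate(CANONICAL_VARIABLES)}
    v_rows, f_rows, o_rows = [], [], []
    for rec in sorted(records, key=lambda r: r.patient_id):
        for var in sorted(rec.series, key=var_order.__getitem__):
            s = rec.series[var]
            for t, v in zip(s.times, s.values):
                v_rows.append((rec.patient_id, var, float(t), float(v)))
        for ev in sorted(rec.fluids, key=lambda e: e.time):
            f_rows.append((rec.patient_id, float(ev.time), float(ev.volume)))
        o_rows.append((rec.patient_id, rec.age_years, rec.icu_stay_h,
                       rec.death_time_h))
    # %.17g round-trips doubles exactly, so read_cohort(write_cohort(r))
    # reproduces every field bit-for-bit
    fmt = "%.17g"
    pd.DataFrame(v_rows, columns=_VITALS_COLS).to_csv(
        vitals_path, index=False, float_format=fmt)
    pd.DataFrame(f_rows, columns=_FLUIDS_COLS).to_csv(
        fluids_path, index=False, float_format=fmt)
    pd.DataFrame(o_rows, columns=_OUTCOMES_COLS).to_csv(
        outcomes_path, index=False, float_format=fmt)
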