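"""Summary indexes on the first 48 h after shock onset, and cohort assembly.

Nine statistics (mean, std, min, max, median, kurtosis, skewness, slope,
delta) are computed for each of the 15 canonical variables, giving 135 named
indexes per patient.  Patients are labelled NS when death occurs within
7 days (168 h) of onset, else S.  The cohort matrix replaces missing values
with per-feature means across the observed patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CANONICAL_VARIABLES, PatientRecord, VitalSeries

#: Statistic names, in reporting order.
STATS: tuple[str, ...] = (
    "mean", "std", "min", "max", "median",
    "kurtosis", "skewness", "slope", "delta",
)

#: Feature names in canonical order: variable-major, statistic-minor.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{var}" for var in CANONICAL_VARIABLES for stat in STATS
)

WINDOW_H = 48.0
MORTALITY_HORIZON_H = 168.0  # 7 days

SURVIVOR = "S"
NONSURVIVOR = "NS"


def window_series(
    record: PatientRecord, onset_h: float, width_h: float = WINDOW_H
) -> dict[str, VitalSeries]:
    """Restrict every series to [onset, onset + width], closed endpoints.

    Times are re-expressed as hours since onset.  Variables with no sample
    in the window are absent from the result.
    """
    out: dict[str, VitalSeries] = {}
    for var, s in record.series.items():
        keep = (s.times >= onset_h) & (s.times <= onset_h + width_h)
        if keep.any():
            out[var] = VitalSeries(var, s.times[keep] - onset_h,
                                   s.values[keep])
    return out


def summarize_series(series: VitalSeries) -> dict[str, float | None]:
    """The nine summary statistics of one within-window series.

    std is the sample (n-1) standard deviation; skewness and kurtosis are
    the population moment ratios (kurtosis non-excess, so a Gaussian tends
    to 3); slope is the OLS slope of value against time in units per hour;
    delta is the last minus the first observed value.  Statistics whose
    minimum sample count (1 for mean/min/max/median, 2 for std/slope/delta,
    3 for skewness, 4 for kurtosis) is not met are None, as are skewness
    and kurtosis of a zero-variance series.
    """
    t, v = series.times, series.values
    n = len(v)
    out: dict[str, float | None] = {stat: None for stat in STATS}
    if n == 0:
        return out
    out["mean"] = float(np.mean(v))
    out["min"] = float(np.min(v))
    out["max"] = float(np.max(v))
    out["median"] = float(np.median(v))
    if n >= 2:
        out["std"] = float(np.std(v, ddof=1))
        out["delta"] = float(v[-1] - v[0])
        out["slope"] = float(np.polyfit(t, v, 1)[0])
    constant = n >= 2 and np.ptp(v) == 0
    if constant:
        out["slope"] = 0.0
    if n >= 3 and not constant:
        out["skewness"] = float(sps.skew(v, bias=True))
    if n >= 4 and not constant:
        out["kurtosis"] = float(sps.kurtosis(v, fisher=False, bias=True))
    return out


def mortality_label(
    record: PatientRecord, onset_h: float,
    horizon_h: float = MORTALITY_HORIZON_H,
) -> str:
    """NS iff death occurs within ``horizon_h`` of onset (boundary NS)."""
    if (record.death_time_h is not None
            and record.death_time_h <= onset_h + horizon_h):
        return NONSURVIVOR
    return SURVIVOR


@dataclass(frozen=True)
class FeatureVector:
    """The 135 named indexes plus the 7-day mortality label."""

    patient_id: str
    values: dict[str, float | None]
    label: str

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature keys mismatch (missing={sorted(missing)[:3]}, "
                f"extra={sorted(extra)[:3]})"
            )
        if self.label not in (SURVIVOR, NONSURVIVOR):
            raise ValueError(f"label must be S or NS, got {self.label!r}")


def extract_features(
    record: PatientRecord, onset_h: float,
    width_h: float = WINDOW_H, horizon_h: float = MORTALITY_HORIZON_H,
) -> FeatureVector:
    """All 135 indexes of the post-onset window, plus the mortality label."""
    windowed = window_series(record, onset_h, width_h)
    values: dict[str, float | None] = {}
    for var in CANONICAL_VARIABLES:
        s = windowed.get(var)
        stats = summarize_series(s) if s is not None else dict.fromkeys(STATS)
        for stat in STATS:
            values[f"{stat}_{var}"] = stats[stat]
    return FeatureVector(record.patient_id, values,
                         mortality_label(record, onset_h, horizon_h))


@dataclass
class CohortMatrix:
    """Patients x features with missingness mask and imputation record."""

    feature_names: tuple[str, ...]
    patient_ids: tuple[str, ...]
    X: np.ndarray                     # imputed, no NaN
    labels: tuple[str, ...]
    missing_mask: np.ndarray          # True where a value was imputed
    imputed_means: dict[str, float] = field(default_factory=dict)

    @property
    def y(self) -> np.ndarray:
        """Labels coded 0 (S) / 1 (NS)."""
        return np.array([1.0 if lb == NONSURVIVOR else 0.0
                         for lb in self.labels])

    def to_frame(self, imputed: bool = True) -> pd.DataFrame:
        """Wide-format data frame; un-imputed cells NaN when requested."""
        X = self.X.copy()
        if not imputed:
            X[self.missing_mask] = np.nan
        df = pd.DataFrame(X, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.insert(0, "patient_id", list(self.patient_ids))
        return df


def assemble_matrix(feature_vectors: list[FeatureVector]) -> CohortMatrix:
    """Stack feature vectors and mean-impute missing entries.

    Missing cells are replaced with the across-patient mean of the observed
    values of that feature (so column means are unchanged).  A feature
    observed for no patient is an error.
    """
    if len(feature_vectors) < 2:
        raise ValueError("need at least 2 feature vectors")
    names = FEATURE_NAMES
    X = np.full((len(feature_vectors), len(names)), np.nan)
    for i, fv in enumerate(feature_vectors):
        for j, name in enumerate(names):
            val = fv.values[name]
            if val is not None:
                X[i, j] = val
    mask = np.isnan(X)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = names[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"feature {bad!r} missing for all patients")
    means = np.nanmean(X, axis=0)
    X[mask] = np.broadcast_to(means, X.shape)[mask]
    return CohortMatrix(
        feature_names=names,
        patient_ids=tuple(fv.patient_id for fv in feature_vectors),
        X=X,
        labels=tuple(fv.label for fv in feature_vectors),
        missing_mask=mask,
        imputed_means={name: float(m) for name, m in zip(names, means)},
    )
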