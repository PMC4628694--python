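"""Synthetic cohort generator with known ground truth.

Each generated patient carries a SIRS-type abnormality period (elevated
temperature, heart rate, respiratory rate and WBC), two prolonged
hypotension episodes inside it — a decoy whose fluid window stays at or
below the 600 mL threshold and a true onset episode with a qualifying
bolus — plus configurable survivor/nonsurvivor effects planted in the 48 h
window after the true onset.  Series are piecewise-constant baselines with
per-patient random offsets, Gaussian noise, and ramp excursions for slope
effects; sampling is irregular with exponential inter-arrival times,
sparser for laboratory variables than for monitored ones.

Generation is a pure function of the spec (including its seed), so the
detector, the screen and the model can all be validated against the
recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import CANONICAL_VARIABLES, FluidEvent, PatientRecord, VitalSeries
from .features import NONSURVIVOR, SURVIVOR

#: Mean inter-sample interval (h) per variable: monitor variables dense,
#: laboratory variables sparse.
DEFAULT_SAMPLING_RATES: dict[str, float] = {
    "SBP": 0.5, "DBP": 0.5, "MAP": 0.5, "HR": 0.5, "RR": 0.5,
    "CVP": 1.0, "CO": 2.0, "SpO2": 0.5, "T": 1.0,
    "pH": 6.0, "creatinine": 10.0, "glucose": 6.0, "lactate": 6.0,
    "hematocrit": 8.0, "WBC": 8.0,
}

#: Normal resting level of each variable.
BASELINES: dict[str, float] = {
    "SBP": 115.0, "DBP": 65.0, "MAP": 82.0, "HR": 80.0, "RR": 16.0,
    "CVP": 8.0, "CO": 5.5, "T": 36.8, "pH": 7.38, "creatinine": 1.0,
    "glucose": 120.0, "lactate": 1.5, "hematocrit": 33.0, "WBC": 9000.0,
    "SpO2": 97.0,
}

#: Measurement noise standard deviation.
NOISE_SD: dict[str, float] = {
    "SBP": 4.0, "DBP": 3.0, "MAP": 3.0, "HR": 4.0, "RR": 1.5,
    "CVP": 1.5, "CO": 0.7, "T": 0.2, "pH": 0.03, "creatinine": 0.15,
    "glucose": 15.0, "lactate": 0.3, "hematocrit": 1.5, "WBC": 800.0,
    "SpO2": 1.0,
}

#: Between-patient level heterogeneity.
PATIENT_SD: dict[str, float] = {
    "SBP": 3.0, "DBP": 3.0, "MAP": 3.0, "HR": 5.0, "RR": 1.5,
    "CVP": 1.2, "CO": 0.8, "T": 0.25, "pH": 0.04, "creatinine": 0.2,
    "glucose": 15.0, "lactate": 1.0, "hematocrit": 2.0, "WBC": 1500.0,
    "SpO2": 1.0,
}

#: Level held during the SIRS abnormality period (pre-onset).
SIRS_LEVELS: dict[str, float] = {
    "T": 38.6, "HR": 110.0, "RR": 24.0, "WBC": 15000.0,
}

#: Default planted survivor/nonsurvivor contrasts applied in the post-onset
#: window: level effects for mean_* keys, ramp effects for slope_* keys.
#: Directions and rough magnitudes follow the reported group medians
#: (e.g. NS mean MAP ~64 vs S ~75 mmHg; negative NS BP and SpO2 slopes;
#: elevated NS lactate and CVP).
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "mean_MAP": (75.0, 64.0),
    "mean_SBP": (105.0, 97.0),
    "mean_HR": (103.0, 115.0),
    "mean_lactate": (3.2, 6.7),
    "mean_CVP": (14.3, 17.3),
    "mean_pH": (7.32, 7.22),
    "slope_SBP": (0.33, -0.04),
    "slope_SpO2": (0.0, -0.19),
}

_SLOPE_JITTER_SD = 0.08  # per-patient slope heterogeneity for planted ramps


@dataclass(frozen=True)
class ShockProfile:
    """Placement of the SIRS period, hypotension episodes and boluses.

    Each ``(lo, hi)`` pair is a uniform sampling range in hours.  The decoy
    episode's fluid window receives ``decoy_bolus_ml`` (at most the 600 mL
    threshold) while the onset episode receives ``onset_bolus_ml`` split
    over two events, exercising the qualification rule in both directions.
    """

    sirs_start_h: tuple[float, float] = (5.0, 10.0)
    decoy_offset_h: tuple[float, float] = (2.0, 4.0)
    decoy_duration_h: tuple[float, float] = (1.0, 2.0)
    onset_gap_h: tuple[float, float] = (4.0, 6.0)
    onset_duration_h: tuple[float, float] = (2.0, 4.0)
    hypo_sbp: float = 75.0
    decoy_bolus_ml: float = 200.0
    onset_bolus_ml: float = 900.0

    def validate(self) -> None:
        for name in ("sirs_start_h", "decoy_offset_h", "decoy_duration_h",
                     "onset_gap_h", "onset_duration_h"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"shock profile {name} must satisfy 0 < lo <= hi")
        if self.decoy_duration_h[0] <= 0.5:
            raise ValueError("decoy episodes must exceed 30 minutes")
        if self.onset_duration_h[0] <= 0.5:
            raise ValueError("onset episodes must exceed 30 minutes")
        if self.onset_gap_h[0] <= 2.0:
            raise ValueError(
                "onset_gap_h must exceed 2 h to keep fluid windows disjoint")
        if self.hypo_sbp >= 90.0:
            raise ValueError("hypo_sbp must be below the 90 mmHg threshold")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    n_patients: int = 73
    nonsurvivor_fraction: float = 20.0 / 73.0
    sampling_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RATES))
    effect_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    shock_profile: ShockProfile = field(default_factory=ShockProfile)
    seed: int = 0
    post_onset_margin_h: tuple[float, float] = (4.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 <= self.nonsurvivor_fraction <= 1:
            raise ValueError("nonsurvivor_fraction must be in [0, 1]")
        for var, rate in self.sampling_rates.items():
            if var not in CANONICAL_VARIABLES:
                raise ValueError(f"unknown variable {var!r} in sampling_rates")
            if rate <= 0:
                raise ValueError(f"sampling rate for {var} must be > 0")
        for key, (s_val, ns_val) in self.effect_profile.items():
            stat, _, var = key.partition("_")
            if var not in CANONICAL_VARIABLES or stat not in ("mean", "slope"):
                raise ValueError(
                    f"unsupported planted effect {key!r}: use mean_<var> "
                    f"or slope_<var>")
        self.shock_profile.validate()

    @property
    def planted_features(self) -> tuple[str, ...]:
        return tuple(sorted(
            k for k, (s, ns) in self.effect_profile.items() if s != ns))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    onsets: dict[str, float]            # patient_id -> true onset (h)
    labels: dict[str, str]              # patient_id -> S / NS
    planted_features: tuple[str, ...]


def _sample_times(rng: np.random.Generator, mean_gap: float,
                  stay: float) -> np.ndarray:
    n_draw = int(stay / mean_gap * 1.6) + 20
    gaps = rng.exponential(mean_gap, size=n_draw)
    times = rng.uniform(0, mean_gap) + np.cumsum(gaps) - gaps[0]
    return times[times <= stay]


def _merge_times(random_times: np.ndarray,
                 forced: list[float], stay: float) -> np.ndarray:
    times = np.concatenate([random_times, np.asarray(forced, dtype=float)])
    times = times[(times >= 0) & (times <= stay)]
    times = np.sort(times)
    if len(times) == 0:
        return times
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return times[keep]


def _generate_patient(
    rng: np.random.Generator,
    patient_id: str,
    is_ns: bool,
    spec: CohortSpec,
    planted: bool,
) -> tuple[PatientRecord, float]:
    """One record plus its true onset time."""
    p = spec.shock_profile
    sirs_start = rng.uniform(*p.sirs_start_h)
    d0 = sirs_start + rng.uniform(*p.decoy_offset_h)
    d1 = d0 + rng.uniform(*p.decoy_duration_h)
    onset = d1 + rng.uniform(*p.onset_gap_h)
    o1 = onset + rng.uniform(*p.onset_duration_h)
    stay = onset + 48.0 + rng.uniform(*spec.post_onset_margin_h)
    if stay < 48.0:
        raise ValueError(f"{patient_id}: infeasible spec, stay {stay:.1f} h")

    effects = spec.effect_profile if planted else {}
    side = 1 if is_ns else 0

    series: dict[str, VitalSeries] = {}
    for var in CANONICAL_VARIABLES:
        rate = spec.sampling_rates.get(var, DEFAULT_SAMPLING_RATES[var])
        forced: list[float] = []
        if var in ("T", "HR"):
            forced.append(sirs_start)  # pins the SIRS episode start
        if var == "SBP":
            forced += [d0, d1, onset, o1]  # pins hypotension boundaries
        if var == "WBC":
            # guarantees the >=2 WBC inclusion gate regardless of the
            # sparse random sampling
            forced += [sirs_start + 1.0, min(sirs_start + 13.0, stay)]
        times = _merge_times(_sample_times(rng, rate, stay), forced, stay)
        if len(times) == 0:
            continue

        offset = rng.normal(0.0, PATIENT_SD[var])
        base = BASELINES[var] + offset
        sirs_level = SIRS_LEVELS.get(var)
        mean_key, slope_key = f"mean_{var}", f"slope_{var}"
        if mean_key in effects:
            post = effects[mean_key][side] + offset
        elif sirs_level is not None:
            post = sirs_level + offset
        else:
            post = base
        slope = 0.0
        if slope_key in effects:
            slope = effects[slope_key][side] + rng.normal(0, _SLOPE_JITTER_SD)

        level = np.full(len(times), base)
        in_sirs = times >= sirs_start
        if sirs_level is not None:
            level[in_sirs & (times < onset)] = sirs_level + offset
        post_mask = times >= onset
        level[post_mask] = post + slope * (times[post_mask] - onset)
        values = level + rng.normal(0.0, NOISE_SD[var], len(times))
        if var == "SBP":
            hypo = ((times >= d0) & (times < d1)) | \
                   ((times >= onset) & (times < o1))
            values[hypo] = p.hypo_sbp + rng.normal(0, 2.0, int(hypo.sum()))
        series[var] = VitalSeries(var, times, values)

    fluids = [
        FluidEvent(d0 + 0.1 * (d1 - d0), p.decoy_bolus_ml),
        FluidEvent(onset - 0.5, p.onset_bolus_ml / 2.0),
        FluidEvent(onset + 0.25 * (o1 - onset), p.onset_bolus_ml / 2.0),
    ]
    death = float(onset + rng.uniform(24.0, 160.0)) if is_ns else None
    record = PatientRecord(
        patient_id=patient_id,
        series=series,
        fluids=sorted(fluids, key=lambda e: e.time),
        icu_stay_h=float(stay),
        death_time_h=death,
        age_years=float(np.round(rng.uniform(18.0, 90.0), 1)),
    )
    return record, float(onset)


def _labels(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    n_ns = int(round(spec.n_patients * spec.nonsurvivor_fraction))
    flags = np.zeros(spec.n_patients, dtype=bool)
    flags[:n_ns] = True
    rng.shuffle(flags)
    return flags


def _generate(spec: CohortSpec,
              planted: bool) -> tuple[list[PatientRecord], GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    ns_flags = _labels(rng, spec)
    width = len(str(spec.n_patients))
    records, onsets, labels = [], {}, {}
    for i, is_ns in enumerate(ns_flags):
        pid = f"p{i + 1:0{width}d}"
        rec, onset = _generate_patient(rng, pid, bool(is_ns), spec, planted)
        records.append(rec)
        onsets[pid] = onset
        labels[pid] = NONSURVIVOR if is_ns else SURVIVOR
    truth = GroundTruth(onsets, labels,
                        spec.planted_features if planted else ())
    return records, truth


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a cohort with planted survivor/nonsurvivor effects.

    Every record passes the inclusion criteria, contains a decoy and a
    fluid-qualified hypotension episode inside a SIRS period, and the true
    onset and label are recorded.  Deterministic in ``spec.seed``.
    """
    return _generate(spec, planted=True)


def generate_null_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientRecord], GroundTruth]:
    """As :func:`generate_cohort` but with no planted effects.

    All series are drawn from the survivor distribution regardless of the
    label, so labels are independent of every feature; death times still
    respect the 7-day labelling rule.
    """
    return _generate(spec, planted=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground-truth table ``patient_id,true_onset_h,label`` plus a planted
    feature list on comment lines."""
    with open(path, "w") as fh:
        for name in truth.planted_features:
            fh.write(f"# planted: {name}\n")
        fh.write("patient_id,true_onset_h,label\n")
        for pid in sorted(truth.onsets):
            fh.write(f"{pid},{truth.onsets[pid]!r},{truth.labels[pid]}\n")


def read_ground_truth(path) -> GroundTruth:
    planted: list[str] = []
    onsets: dict[str, float] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# planted:"):
                planted.append(line.split(":", 1)[1].strip())
            elif line and not line.startswith(("#", "patient_id")):
                pid, onset, label = line.split(",")
                onsets[pid] = float(onset)
                labels[pid] = label
    return GroundTruth(onsets, labels, tuple(planted))
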