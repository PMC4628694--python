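"""Rule-based detection of SIRS abnormality episodes and septic-shock onset.

Point measurements are turned into time intervals with *sample-and-hold*
semantics: a value persists from its timestamp until the next measurement of
the same variable, and the last value is held to the end of the ICU stay.

The abnormality criteria are the four SIRS gates (temperature > 38 degC or
< 36 degC; heart rate > 90 bpm; respiratory rate > 20 breaths/min; white
blood cell count > 12000 or < 4000 cells/cmm).  Intervals on which at least
``min_criteria`` gates hold simultaneously are backtracked to the earliest
time from which a contributing gate is continuously abnormal, merged when
less than 6 h apart, and kept only when longer than 5 h.

Shock onset is the start of the earliest *sepsis-induced hypotension*
episode: a prolonged (>= 30 min) interval of SBP < 90 mmHg overlapping an
abnormality episode, during whose fluid window (1 h before the episode start
to halfway through the episode) more than 600 mL of fluids were given.
Records with fewer than two prolonged hypotension episodes are considered
to have no shock episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .cohort import FluidEvent, PatientRecord, VitalSeries

Interval = tuple[float, float]

ABNORMALITY = "abnormality"
HYPOTENSION = "hypotension"
SEPSIS_INDUCED = "sepsis_induced_hypotension"


@dataclass(frozen=True)
class SirsConfig:
    """Thresholds and episode rules for SIRS abnormality detection."""

    temp_high: float = 38.0
    temp_low: float = 36.0
    hr_thresh: float = 90.0
    rr_thresh: float = 20.0
    wbc_high: float = 12000.0
    wbc_low: float = 4000.0
    min_criteria: int = 2      # standard SIRS; set 4 for the all-four reading
    min_episode_h: float = 5.0
    merge_gap_h: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.temp_low < self.temp_high):
            raise ValueError("need 0 < temp_low < temp_high")
        if not (0 < self.wbc_low < self.wbc_high):
            raise ValueError("need 0 < wbc_low < wbc_high")
        if min(self.hr_thresh, self.rr_thresh, self.min_episode_h,
               self.merge_gap_h) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_criteria not in (1, 2, 3, 4):
            raise ValueError("min_criteria must be in 1..4")


@dataclass(frozen=True)
class ShockConfig:
    """Thresholds for prolonged hypotension and fluid qualification."""

    sbp_thresh: float = 90.0
    min_hypo_min: float = 30.0
    fluid_pre_h: float = 1.0
    fluid_thresh_ml: float = 600.0
    #: require the hypotension interval to lie inside an abnormality episode
    #: instead of merely overlapping one.
    require_containment: bool = False

    def __post_init__(self) -> None:
        if min(self.sbp_thresh, self.min_hypo_min, self.fluid_pre_h,
               self.fluid_thresh_ml) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class Episode:
    """A typed time interval found by the detector."""

    start_h: float
    end_h: float
    kind: str
    contributing: frozenset[str] = field(default_factory=frozenset)
    fluid_ml: float | None = None

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError(f"start {self.start_h} must precede end {self.end_h}")
        if self.kind not in (ABNORMALITY, HYPOTENSION, SEPSIS_INDUCED):
            raise ValueError(f"unknown episode kind {self.kind!r}")

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass(frozen=True)
class OnsetResult:
    """Outcome of shock-onset labelling for one patient."""

    onset_h: float | None
    reason: str
    episodes: tuple[Episode, ...]

    def __post_init__(self) -> None:
        if (self.onset_h is not None) != (self.reason == "labeled"):
            raise ValueError("onset_h present iff reason == 'labeled'")


REASONS = ("labeled", "no_sirs", "no_prolonged_hypotension",
           "single_hypotension_episode", "no_fluid_qualified")


def hold_intervals(
    series: VitalSeries,
    predicate: Callable[[float], bool],
    stay_end: float,
) -> list[Interval]:
    """Maximal intervals on which the held value satisfies ``predicate``.

    Each measurement is held from its timestamp to the next one; the last
    measurement is held to ``stay_end``.  An empty series yields no
    intervals.
    """
    n = len(series)
    if n == 0:
        return []
    ok = np.fromiter((bool(predicate(v)) for v in series.values),
                     dtype=bool, count=n)
    bounds = np.append(series.times, max(stay_end, series.times[-1]))
    intervals: list[Interval] = []
    start: float | None = None
    for i in range(n):
        if ok[i] and start is None:
            start = float(bounds[i])
        elif not ok[i] and start is not None:
            intervals.append((start, float(bounds[i])))
            start = None
    if start is not None:
        intervals.append((start, float(bounds[-1])))
    return [(a, b) for a, b in intervals if b > a]


def _criterion_intervals(
    record: PatientRecord, config: SirsConfig
) -> dict[str, list[Interval]]:
    """Abnormal held intervals for each SIRS criterion present."""
    stay = record.icu_stay_h
    out: dict[str, list[Interval]] = {}
    checks: dict[str, tuple[str, Callable[[float], bool]]] = {
        "temperature": ("T", lambda v: v > config.temp_high or v < config.temp_low),
        "heart_rate": ("HR", lambda v: v > config.hr_thresh),
        "respiratory_rate": ("RR", lambda v: v > config.rr_thresh),
        "wbc": ("WBC", lambda v: v > config.wbc_high or v < config.wbc_low),
    }
    for criterion, (var, pred) in checks.items():
        s = record.series.get(var)
        if s is not None and len(s):
            ivs = hold_intervals(s, pred, stay)
            if ivs:
                out[criterion] = ivs
    return out


def _count_overlay(
    interval_sets: Sequence[list[Interval]], min_count: int
) -> list[Interval]:
    """Maximal intervals on which >= ``min_count`` of the sets cover time."""
    events: list[tuple[float, int]] = []
    for ivs in interval_sets:
        for a, b in ivs:
            events.append((a, +1))
            events.append((b, -1))
    if not events:
        return []
    events.sort()
    out: list[Interval] = []
    count = 0
    seg_start: float | None = None
    i = 0
    while i < len(events):
        t = events[i][0]
        while i < len(events) and events[i][0] == t:
            count += events[i][1]
            i += 1
        if count >= min_count and seg_start is None:
            seg_start = t
        elif count < min_count and seg_start is not None:
            if t > seg_start:
                out.append((seg_start, t))
            seg_start = None
    return out


def merge_intervals(
    intervals: Iterable[Interval], merge_gap_h: float
) -> list[Interval]:
    """Merge intervals whose gap is strictly below ``merge_gap_h``.

    Idempotent: re-running on its own output changes nothing.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a - merged[-1][1] < merge_gap_h:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def detect_abnormality_episodes(
    record: PatientRecord, config: SirsConfig | None = None
) -> list[Episode]:
    """SIRS abnormality episodes with backtracked starts.

    The start of each interval on which ``min_criteria`` gates hold
    simultaneously is moved back to the earliest time from which at least
    one contributing gate is continuously abnormal into the interval; the
    resulting intervals are merged when less than ``merge_gap_h`` apart and
    kept only if strictly longer than ``min_episode_h``.
    """
    config = config or SirsConfig()
    per_criterion = _criterion_intervals(record, config)
    met = _count_overlay(list(per_criterion.values()), config.min_criteria)
    # backtrack each start through any criterion interval covering it
    backtracked: list[Interval] = []
    for s, e in met:
        new_start = s
        for ivs in per_criterion.values():
            for a, b in ivs:
                if a <= s < b:
                    new_start = min(new_start, a)
        backtracked.append((new_start, e))
    merged = merge_intervals(backtracked, config.merge_gap_h)
    episodes = []
    for a, b in merged:
        if b - a <= config.min_episode_h:
            continue
        contributing = frozenset(
            name for name, ivs in per_criterion.items()
            if any(x < b and a < y for x, y in ivs)
        )
        episodes.append(Episode(a, b, ABNORMALITY, contributing))
    return episodes


def detect_hypotension(
    record: PatientRecord, config: ShockConfig | None = None
) -> list[Episode]:
    """Prolonged hypotension: held SBP < threshold for >= ``min_hypo_min``."""
    config = config or ShockConfig()
    sbp = record.series.get("SBP")
    if sbp is None or len(sbp) == 0:
        raise ValueError(f"{record.patient_id}: no SBP series")
    min_h = config.min_hypo_min / 60.0
    ivs = hold_intervals(sbp, lambda v: v < config.sbp_thresh,
                         record.icu_stay_h)
    return [Episode(a, b, HYPOTENSION) for a, b in ivs if b - a >= min_h]


def fluid_intake_in_window(
    fluids: Sequence[FluidEvent],
    episode: Episode,
    config: ShockConfig | None = None,
) -> float:
    """Fluid volume given from 1 h before the episode to its midpoint.

    Both window endpoints are closed; events exactly on a boundary count.
    """
    config = config or ShockConfig()
    lo = episode.start_h - config.fluid_pre_h
    hi = episode.start_h + (episode.end_h - episode.start_h) / 2.0
    return float(sum(ev.volume for ev in fluids if lo <= ev.time <= hi))


def _overlaps(a: Episode, b: Episode, containment: bool) -> bool:
    if containment:
        return b.start_h <= a.start_h and a.end_h <= b.end_h
    return max(a.start_h, b.start_h) < min(a.end_h, b.end_h)


def detect_shock_onset(
    record: PatientRecord,
    sirs_config: SirsConfig | None = None,
    shock_config: ShockConfig | None = None,
) -> OnsetResult:
    """Label the septic-shock onset of one record, if any.

    Hypotension episodes overlapping no abnormality episode are ineligible;
    eligible episodes with window fluid intake strictly above
    ``fluid_thresh_ml`` become sepsis-induced hypotension, and the earliest
    one's start is the onset.  Records with no abnormality episode, fewer
    than two prolonged hypotension episodes, or no fluid-qualified episode
    are labelled with the corresponding reason.
    """
    sirs_config = sirs_config or SirsConfig()
    shock_config = shock_config or ShockConfig()
    abnormal = detect_abnormality_episodes(record, sirs_config)
    hypo = detect_hypotension(record, shock_config)

    annotated: list[Episode] = []
    for ep in hypo:
        intake = fluid_intake_in_window(record.fluids, ep, shock_config)
        eligible = any(_overlaps(ep, ab, shock_config.require_containment)
                       for ab in abnormal)
        kind = (SEPSIS_INDUCED
                if eligible and intake > shock_config.fluid_thresh_ml
                else HYPOTENSION)
        annotated.append(replace(ep, kind=kind, fluid_ml=intake))

    episodes = tuple(sorted(abnormal + annotated,
                            key=lambda e: (e.start_h, e.end_h, e.kind)))
    if not abnormal:
        return OnsetResult(None, "no_sirs", episodes)
    if len(hypo) == 0:
        return OnsetResult(None, "no_prolonged_hypotension", episodes)
    if len(hypo) == 1:
        return OnsetResult(None, "single_hypotension_episode", episodes)
    shocks = [e for e in annotated if e.kind == SEPSIS_INDUCED]
    if not shocks:
        return OnsetResult(None, "no_fluid_qualified", episodes)
    onset = min(e.start_h for e in shocks)
    return OnsetResult(onset, "labeled", episodes)
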