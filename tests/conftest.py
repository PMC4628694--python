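import numpy as np
import pytest

from icushock.cohort import FluidEvent, PatientRecord, VitalSeries


def make_series(variable, times, values):
    return VitalSeries(variable, np.asarray(times, float),
                       np.asarray(values, float))


def make_record(patient_id="p1", stay=72.0, death=None, age=60.0,
                fluids=(), **series_kwargs):
    """Record from keyword series, e.g. HR=([0, 1], [80, 95])."""
    series = {var: make_series(var, t, v)
              for var, (t, v) in series_kwargs.items()}
    return PatientRecord(
        patient_id=patient_id, series=series,
        fluids=[FluidEvent(t, v) for t, v in fluids],
        icu_stay_h=stay, death_time_h=death, age_years=age)


def regular(start, stop, step, value):
    """(times, constant values) pair on a regular grid, stop exclusive."""
    t = np.arange(start, stop, step, dtype=float)
    return t, np.full(len(t), float(value))


@pytest.fixture
def included_record():
    """Minimal record satisfying every inclusion gate exactly."""
    return make_record(
        stay=48.0,
        HR=regular(0, 40, 4, 80),
        T=regular(0, 40, 4, 37),
        SBP=regular(0, 40, 4, 120),
        RR=regular(0, 40, 4, 16),
        WBC=([0.0, 24.0], [9000.0, 9500.0]),
    )


LATTICE = 0.25  # hours; exactly representable, multiple of the 1-min grid


def random_small_record(rng, with_fluids=True, patient_id="r1"):
    """Small record with boundary-rich values on a 0.25 h time lattice.

    Designed for the minute-grid oracle equivalence tests: every sample
    time is a multiple of 0.25 h so episode boundaries land exactly on the
    1-minute grid.
    """
    stay = float(rng.integers(48 * 4, 72 * 4 + 1)) * LATTICE
    n_slots = int(stay / LATTICE)

    def lattice_times(n):
        k = rng.choice(n_slots, size=min(n, n_slots), replace=False)
        return np.sort(k) * LATTICE

    spec = {
        "T": (37.3, 1.5),
        "HR": (90.0, 18.0),
        "RR": (20.0, 6.0),
        "WBC": (10000.0, 5000.0),
        "SBP": (93.0, 14.0),
    }
    series = {}
    for var, (mu, sd) in spec.items():
        n = int(rng.integers(5, 41))
        t = lattice_times(n)
        series[var] = VitalSeries(var, t, rng.normal(mu, sd, len(t)))
    fluids = []
    if with_fluids:
        for _ in range(int(rng.integers(0, 9))):
            fluids.append(FluidEvent(
                float(rng.integers(0, n_slots)) * LATTICE,
                float(rng.uniform(0, 500))))
        fluids.sort(key=lambda e: e.time)
    return PatientRecord(patient_id=patient_id, series=series,
                         fluids=fluids, icu_stay_h=stay, age_years=55.0)
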